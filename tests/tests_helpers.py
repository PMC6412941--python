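"""Small constructors shared by tests."""

from modnmf.enrichment import EnrichmentResult
from modnmf.module_extraction import Module, ModuleSet


def module_with_significant_terms(counts: list[int]) -> ModuleSet:
    """One module per entry, each with that many terms at adjusted p < 0.05."""
    modules = []
    for idx, n_sig in enumerate(counts):
        terms = [EnrichmentResult(f"T{idx}_{i}", 3, 5, 10, 100, 1e-6, 1e-4)
                 for i in range(n_sig)]
        modules.append(Module(
            index=idx,
            members={"mRNA": [], "circRNA": [], "miRNA": [], "pathway": []},
            chosen_top_percent=10, enriched_terms=terms))
    return ModuleSet(modules=modules, universe={})
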