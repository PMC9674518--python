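"""thyrotype: transcriptome-based molecular subtyping of thyroid nodules.

Library layout:

* :mod:`thyrotype.core_io` — expression/metadata/GMT readers, run config, RNG
* :mod:`thyrotype.synthetic_data` — planted-truth cohort generators
* :mod:`thyrotype.subtyping` — gene filtering, consensus NMF, exemplar genes,
  marker selection, nearest-template transfer
* :mod:`thyrotype.scoring` — TDS, single-sample enrichment, group statistics
* :mod:`thyrotype.network` — MI network, DPI pruning, MCC hubs, GSEA
* :mod:`thyrotype.trajectory` — pseudotime backbone, branch DE, gene clusters
* :mod:`thyrotype.variant_filters` — fusion/mutation post-call filters
* :mod:`thyrotype.diagnosis` — DE, RFE signature, multi-classifier ROC
"""

from importlib import resources as _resources

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    read_expression_matrix,
    read_gmt,
    read_sample_table,
    log2_transform,
    rng_for,
)

__version__ = "0.1.0"


def load_default_gene_sets() -> GeneSetCollection:
    """The packaged TDS/immune/stromal/GEP gene sets (editable defaults)."""
    with _resources.as_file(
        _resources.files("thyrotype.data") / "default_sets.gmt"
    ) as path:
        return read_gmt(path)
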