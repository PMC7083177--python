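"""admeta: cross-study transcriptomic meta-analysis and disease-module detection.

The pipeline mirrors an evidence-synthesis workflow for case–control
brain transcriptomics: per-study normalization and DEG calling,
event-based log-odds-ratio random-effects meta-analysis across studies,
brain-region subgroup concordance, hypergeometric pathway enrichment, and
DIAMOnD module detection with hub extraction on a STRING-style
interactome. A synthetic-data module generates multi-study cohorts with
known ground truth so every stage is testable offline.
"""

from importlib import resources

__version__ = "0.1.0"


def demo_config_path() -> str:
    """Path to the bundled demo run configuration."""
    return str(resources.files("admeta").joinpath("configs/demo.yaml"))
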