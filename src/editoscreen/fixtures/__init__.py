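"""Packaged reference data: the published table of 59 mammalian
evolutionarily conserved editing sites, plus the source-catalog sizes used
for share computations.

The merged human editing catalog is reported with two totals in the source
literature (1,432,743 and 1,432,744); both are recorded without resolving
the discrepancy.  Share computations use the larger figure.
"""

from importlib import resources

from ..io_formats import SiteRecord, read_site_table

__all__ = [
    "load_ess_table1",
    "HUMAN_DATASET_SIZE",
    "HUMAN_DATASET_SIZE_ALT",
    "MOUSE_DATASET_SIZE",
]

HUMAN_DATASET_SIZE = 1_432_744
HUMAN_DATASET_SIZE_ALT = 1_432_743
MOUSE_DATASET_SIZE = 10_210


def load_ess_table1() -> list[SiteRecord]:
    """The 59 human sites of the conserved (ESS) catalog."""
    ref = resources.files(__package__) / "ess_table1.tsv"
    with resources.as_file(ref) as path:
        return read_site_table(path, dialect="table1_tsv")
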