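"""Bundled reference catalogs.

``load_lung_editing_sites`` returns the published catalog of sixteen
high-confidence A-to-I miRNA editing sites detected in human lung
small RNA-seq cohorts, with each site's 5' shift, edited position
(isomiR coordinates) and the nucleotides adjacent to the edited
adenosine (drawn from the precursor when outside the mature miRNA).

``LUNG_HIGH_CONFIDENCE_COUNTS`` holds the sizes of the corresponding
high-confidence lung catalog by class (isomiR types and miRNAs); the
isomiR share of unique high-confidence sequences follows from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_lung_editing_sites", "LUNG_HIGH_CONFIDENCE_COUNTS", "isomir_share"]

LUNG_HIGH_CONFIDENCE_COUNTS = {
    "EDIT_AI": 16,
    "FIVE_PRIME": 213,
    "NTA_A": 128,
    "NTA_U": 100,
    "MIRNA": 654,
}


def load_lung_editing_sites() -> pd.DataFrame:
    """The 16-site human-lung A-to-I editing catalog as a DataFrame
    suitable for :func:`isomirome.modification_stats.summarize_catalog`."""
    with resources.files("isomirome.data").joinpath("lung_editing_sites.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def isomir_share(counts: dict | None = None) -> float:
    """Fraction of unique high-confidence sequences that are isomiRs
    rather than canonical miRNAs."""
    counts = counts or LUNG_HIGH_CONFIDENCE_COUNTS
    isomirs = sum(v for k, v in counts.items() if k != "MIRNA")
    return isomirs / (isomirs + counts.get("MIRNA", 0))
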