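"""Published study tables, loaded as inputs.

The Seychelles caecilian platform-comparison study printed three small
tables that this package consumes directly: the 16-window divergence
partition of the pooled-HiSeq reference alignment (circular coordinates,
origin at the start of the trnF tRNA gene, alignment length 16,440
columns), the per-platform phantom-nucleotide counts for the three
multi-platform specimens, and the per-platform read counts and mean read
lengths behind the coverage summaries.  GenBank accessions for the
underlying mitogenomes (KU753811-KU753817, KU974367, GQ244470, GQ244472,
GQ244475, KF540152, KF540154, KF540162) are listed for provenance; the
sequences themselves are not shipped.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .reduction import Window

__all__ = [
    "HISEQ_ALIGNMENT_LENGTH",
    "load_hiseq_windows",
    "load_phantom_counts",
    "load_platform_coverage",
]

#: Columns in the reference alignment the window scheme partitions.
HISEQ_ALIGNMENT_LENGTH = 16440


def _data(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("mitopool.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_hiseq_windows() -> list[Window]:
    """The 16 divergence windows of the pooled-HiSeq reduction, with their
    printed maximum p-distances (as fractions)."""
    df = _data("hiseq_windows.tsv")
    return [
        Window(start=int(r.start), end=int(r.end),
               max_p_distance=float(r.max_divergence_percent) / 100.0)
        for r in df.itertuples()
    ]


def load_phantom_counts() -> pd.DataFrame:
    """Phantom single-nucleotide counts per specimen x platform (rows A, C,
    G, T, N, insertions added, and the reconstructed length)."""
    return _data("phantom_counts.tsv")


def load_platform_coverage() -> pd.DataFrame:
    """Reads used and mean read length per specimen x platform."""
    return _data("platform_coverage.tsv")
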