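"""The two data transforms underlying both fractal models.

Model 1 works on magnitudes ``|FC - 1|`` ranked ascending within one
breed/tissue (housekeeping gene excluded).  Model 2 recodes each signed FC
into a signed log2 value LG (negative for upregulated genes, positive for
downregulated ones), shifts the panel so its minimum is zero, and reads the
fractional parts of the shifted values as portrait x-coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_model import FCTable

__all__ = [
    "RankedSeries",
    "RankedEntry",
    "PortraitPoint",
    "fc_to_magnitude",
    "fc_to_lg",
    "rank_series",
    "build_portrait",
]


@dataclass(frozen=True)
class RankedEntry:
    gene: str
    magnitude: float
    rank: int


@dataclass(frozen=True)
class RankedSeries:
    """Per breed/tissue magnitudes ``|FC - 1|`` with ascending 1-based ranks."""

    breed: str
    tissue: str
    entries: tuple[RankedEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def magnitudes(self, lo: int = 1, hi: int | None = None) -> list[float]:
        """Magnitudes of ranks lo..hi inclusive (default: all)."""
        hi = len(self.entries) if hi is None else hi
        if not (1 <= lo <= hi <= len(self.entries)):
            raise ValueError(
                f"rank range [{lo}:{hi}] outside series of length "
                f"{len(self.entries)} ({self.breed}/{self.tissue})"
            )
        return [e.magnitude for e in self.entries[lo - 1:hi]]


@dataclass(frozen=True)
class PortraitPoint:
    """One gene in a fractal portrait.

    ``lg`` is the signed log2 recoding of FC; ``y = lg - min(lg)`` over the
    panel; ``x = y - floor(y)`` is the fractional part, in [0, 1).
    """

    gene: str
    lg: float
    y: float
    x: float


def fc_to_magnitude(fc: float) -> float:
    """Sign-neutral expression-change size ``|fc - 1|``.

    An upregulated gene at fc = 6 and a downregulated one at fc = -4 both
    map to magnitude 5; the housekeeping reference (fc = 1) maps to 0.
    """
    if fc == 0 or not math.isfinite(fc):
        raise ValueError(f"fc must be finite and nonzero, got {fc!r}")
    return abs(fc - 1)


def fc_to_lg(fc: float) -> float:
    """Signed log2 recoding of a signed fold change.

    Upregulated (fc > 0) genes map to ``-log2(fc)``; downregulated (fc < 0)
    genes map to ``+log2(|fc|)``.  The housekeeping reference maps to 0.
    """
    if fc == 0 or not math.isfinite(fc):
        raise ValueError(f"fc must be finite and nonzero, got {fc!r}")
    if fc > 0:
        return -math.log2(fc)
    return math.log2(-fc)


def rank_series(table: FCTable, breed: str, tissue: str) -> RankedSeries:
    """Ascending magnitude ranking of one breed/tissue panel.

    The housekeeping gene is excluded.  Ties are broken by input row order
    (stable sort), making the ranking deterministic.
    """
    records = [r for r in table.select(breed, tissue)
               if r.gene != table.housekeeping_gene]
    if not records:
        raise ValueError(f"no non-housekeeping genes for {breed}/{tissue}")
    ordered = sorted(records, key=lambda r: fc_to_magnitude(r.fc))
    entries = tuple(
        RankedEntry(gene=r.gene, magnitude=fc_to_magnitude(r.fc), rank=i + 1)
        for i, r in enumerate(ordered)
    )
    return RankedSeries(breed=breed, tissue=tissue, entries=entries)


def build_portrait(table: FCTable, breed: str, tissue: str) -> list[PortraitPoint]:
    """Portrait coordinates for one breed/tissue panel.

    The housekeeping gene is included (at lg = 0, implied fc = 1 when the
    table does not store it), so the reference panel has 8 points.  After
    the min-shift the smallest y is exactly 0.
    """
    records = table.select(breed, tissue)
    genes = [r.gene for r in records]
    lgs = [fc_to_lg(r.fc) for r in records]
    if table.housekeeping_gene not in genes:
        genes.append(table.housekeeping_gene)
        lgs.append(0.0)
    lo = min(lgs)
    points = []
    for gene, lg in zip(genes, lgs):
        y = lg - lo
        x = y - math.floor(y)
        points.append(PortraitPoint(gene=gene, lg=lg, y=y, x=x))
    return points
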