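"""Domain types and tabular I/O for fold-change expression panels.

The central object is an :class:`FCTable`: a panel of signed qPCR fold-change
(FC) values keyed by (breed, tissue, gene).  The signed convention encodes an
x-fold downregulated gene as ``-x`` and keeps the housekeeping reference at
``FC = 1`` (stored implicitly: the housekeeping gene may be absent from the
table).  Values in the open interval (-1, 1), excluding 0, are legal but
suspicious under this convention and raise a warning.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "TISSUES",
    "FCRecord",
    "FCTable",
    "PhenotypeRecord",
    "RankWindow",
    "FCValidationError",
    "FCFormatError",
    "read_fc_table",
    "read_phenotype_table",
    "write_report",
    "read_report",
]

TISSUES = ("breast", "thigh")


class FCValidationError(ValueError):
    """A fold-change table violates a domain invariant."""


class FCFormatError(ValueError):
    """An input file does not match the expected tabular schema."""


@dataclass(frozen=True)
class FCRecord:
    """One signed fold-change observation.

    Parameters
    ----------
    breed, gene : str
        Free-string identifiers.
    tissue : str
        One of ``"breast"`` or ``"thigh"``.
    fc : float
        Signed fold change; positive = upregulated x-fold, negative =
        downregulated x-fold, housekeeping reference = 1.  Zero is invalid.
    """

    breed: str
    tissue: str
    gene: str
    fc: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FCValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if not math.isfinite(self.fc) or self.fc == 0:
            raise FCValidationError(
                f"fc must be finite and nonzero, got {self.fc!r} "
                f"({self.breed}/{self.tissue}/{self.gene})"
            )
        if abs(self.fc) < 1:
            warnings.warn(
                f"|fc| < 1 for {self.breed}/{self.tissue}/{self.gene} "
                f"(fc={self.fc}); the signed-FC convention encodes x-fold "
                "downregulation as -x, so magnitudes below 1 are unusual",
                stacklevel=2,
            )


class FCTable:
    """An ordered collection of :class:`FCRecord` with unique keys.

    Input row order is preserved; downstream ranking uses it as the
    deterministic tie-breaker.  Every (breed, tissue) group must contain the
    same gene set.  The housekeeping gene (default ``TBP``) is implied at
    ``fc = 1`` when absent.
    """

    def __init__(
        self, records: Iterable[FCRecord], housekeeping_gene: str = "TBP"
    ) -> None:
        self.records: list[FCRecord] = list(records)
        self.housekeeping_gene = housekeeping_gene
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            key = (rec.breed, rec.tissue, rec.gene)
            if key in seen:
                raise FCValidationError(f"duplicate record for {key}")
            seen.add(key)
        genesets = {
            group: frozenset(r.gene for r in self.records
                             if (r.breed, r.tissue) == group)
            for group in {(r.breed, r.tissue) for r in self.records}
        }
        if len(set(genesets.values())) > 1:
            shapes = sorted({tuple(sorted(g)) for g in genesets.values()})
            raise FCValidationError(
                "all (breed, tissue) groups must share the same gene set; "
                f"found {shapes!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FCRecord]:
        return iter(self.records)

    @property
    def breeds(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.breed not in out:
                out.append(rec.breed)
        return out

    def tissues(self, breed: str) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.breed == breed and rec.tissue not in out:
                out.append(rec.tissue)
        return out

    def select(self, breed: str, tissue: str) -> list[FCRecord]:
        """Records for one breed/tissue, in input order."""
        found = [r for r in self.records
                 if r.breed == breed and r.tissue == tissue]
        if not found:
            raise KeyError(f"no records for breed={breed!r} tissue={tissue!r}")
        return found

    def fc(self, breed: str, tissue: str, gene: str) -> float:
        if gene == self.housekeeping_gene:
            hk = [r for r in self.records
                  if r.breed == breed and r.tissue == tissue
                  and r.gene == gene]
            if not hk:
                return 1.0
            return hk[0].fc
        for rec in self.select(breed, tissue):
            if rec.gene == gene:
                return rec.fc
        raise KeyError(f"no record for {breed}/{tissue}/{gene}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.breed, r.tissue, r.gene, r.fc) for r in self.records],
            columns=["breed", "tissue", "gene", "fc"],
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Breed-level phenotype and embryonic NO-metabolism scores.

    Body weights are grams at 1, 14 and 28 days post hatch; ``nod`` and
    ``nitrate`` are E7 embryonic concentrations in µM of NO-donor compounds
    and nitrate.  ``breed_type`` is the utility category (meat, dual_purpose,
    egg, game).  Derived ratios (growth rates, NO oxidation) live in
    :mod:`myofractal.phenotype_stats`.
    """

    breed: str
    bw1: float
    bw14: float
    bw28: float
    nod: float
    nitrate: float
    breed_type: str
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bw1", "bw14", "bw28"):
            if getattr(self, name) <= 0:
                raise FCValidationError(f"{name} must be positive for {self.breed}")
        if self.nod < 0 or self.nitrate < 0:
            raise FCValidationError(f"NO metabolite levels must be >= 0 for {self.breed}")


@dataclass(frozen=True)
class RankWindow:
    """Inclusive 1-based range of gene ranks used by a log-log dimension fit."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise FCValidationError(f"invalid rank window [{self.lo}:{self.hi}]")
        if self.hi - self.lo + 1 < 3:
            raise FCValidationError(
                f"rank window [{self.lo}:{self.hi}] must span at least 3 ranks"
            )

    @property
    def ranks(self) -> range:
        return range(self.lo, self.hi + 1)

    def __len__(self) -> int:
        return self.hi - self.lo + 1

    def __str__(self) -> str:  # Table-4 style
        return f"[{self.lo}:{self.hi}]"


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_fc_table(
    path: str | Path, sep: str | None = None, housekeeping_gene: str = "TBP"
) -> FCTable:
    """Read an expression table (columns breed, tissue, gene, fc).

    The delimiter is inferred from the file suffix (``.tsv`` → tab,
    otherwise comma) unless given.  Raises :class:`FCFormatError` on a
    missing column and :class:`FCValidationError` on bad values, naming
    the offending row.
    """
    df = _read_table(path, sep)
    required = ["breed", "tissue", "gene", "fc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FCFormatError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                FCRecord(str(row["breed"]), str(row["tissue"]),
                         str(row["gene"]), float(row["fc"]))
            )
        except FCValidationError as err:
            raise FCValidationError(f"{path}, row {idx + 2}: {err}") from err
    return FCTable(records, housekeeping_gene=housekeeping_gene)


def read_phenotype_table(path: str | Path, sep: str | None = None) -> list[PhenotypeRecord]:
    """Read a phenotype table (columns breed, bw1, bw14, bw28, nod, nitrate, breed_type)."""
    df = _read_table(path, sep)
    required = ["breed", "bw1", "bw14", "bw28", "nod", "nitrate", "breed_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FCFormatError(f"{path}: missing column(s) {missing}")
    return [
        PhenotypeRecord(
            breed=str(row["breed"]),
            bw1=float(row["bw1"]), bw14=float(row["bw14"]), bw28=float(row["bw28"]),
            nod=float(row["nod"]), nitrate=float(row["nitrate"]),
            breed_type=str(row["breed_type"]),
        )
        for _, row in df.iterrows()
    ]


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def write_report(
    results: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    precision: int = 6,
) -> None:
    """Write model results with a deterministic column order.

    Floats are emitted with ``precision`` significant digits (default 6).
    ``format`` is ``"tsv"`` or ``"json"``; JSON round-trips through
    :func:`read_report`.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: _round_sig(float(v), precision))
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {"columns": list(df.columns),
                   "rows": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown report format {format!r}")
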