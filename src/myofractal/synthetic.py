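"""Synthetic fold-change panels with the structure each model assumes.

Three generators mirror the three modelled structures: rank-exponential
magnitude growth ``m_N = a + K*e**N`` (with optional additive Gaussian
noise), power-law growth ``m_N = c*N**D`` (with optional multiplicative
log-normal noise, keeping positivity), and portrait panels with a planted
arithmetic progression of LG values.  Magnitudes are encoded back to
signed fold changes so that the forward transforms recover the generated
latent values exactly; the up/down sign assignment is part of the seeded
stream and carries no model structure.

Identical specs produce identical tables (all randomness flows from
``numpy.random.default_rng(seed)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import FCRecord, FCTable
from .portrait_fractals import DEFAULT_LINE_TOL, detect_collinear_sets
from .transforms import build_portrait

__all__ = [
    "SynthSpec",
    "GenerationError",
    "generate_rank_exponential",
    "generate_power_law",
    "generate_portrait_panel",
    "generate",
]


class GenerationError(RuntimeError):
    """A synthetic panel could not be built under the given constraints."""


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic panel.

    ``model`` selects the generator; ``params`` supplies its parameters:
    (a, K) for ``rank_exponential``, (c, D) for ``power_law`` and
    (n_members, common_difference) for ``portrait_ap``.  For the portrait
    model ``n_genes`` counts the whole panel including the housekeeping
    gene; for the magnitude models it counts the measured genes.
    """

    n_breeds: int
    n_genes: int
    model: str
    params: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 1 or self.n_genes < 1:
            raise ValueError("n_breeds and n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model not in ("rank_exponential", "power_law", "portrait_ap"):
            raise ValueError(f"unknown model {self.model!r}")


def _encode_fc(m: float, rng: np.random.Generator) -> float:
    """Signed-FC encoding of a magnitude so that |fc - 1| = m exactly.

    Upregulated encoding is 1 + m; downregulated is 1 - m, used only when
    m > 2 so |fc| stays >= 1 under the signed convention.  The direction is
    a fair coin from the seeded stream.
    """
    if m > 2 and rng.random() < 0.5:
        return 1.0 - m
    return 1.0 + m


def _magnitude_table(spec: SynthSpec, latent) -> FCTable:
    rng = np.random.default_rng(spec.seed)
    records = []
    for b in range(spec.n_breeds):
        breed = f"S{b + 1}"
        for tissue in ("breast", "thigh"):
            for n in range(1, spec.n_genes + 1):
                m = latent(n, rng)
                if m < 0:
                    raise GenerationError(
                        f"negative magnitude {m:.4g} at rank {n}; "
                        "adjust parameters or noise_sd"
                    )
                records.append(
                    FCRecord(breed, tissue, f"G{n}", _encode_fc(m, rng))
                )
    return FCTable(records)


def generate_rank_exponential(spec: SynthSpec) -> FCTable:
    """Magnitudes a + K*e**N with additive Gaussian noise of sd ``noise_sd``."""
    if spec.model != "rank_exponential":
        raise ValueError("spec.model must be 'rank_exponential'")
    a = float(spec.params.get("a", 0.0))
    K = float(spec.params.get("K", 0.1))
    if a + K * math.e < 0:
        raise GenerationError("parameters yield a negative rank-1 magnitude")

    def latent(n: int, rng: np.random.Generator) -> float:
        m = a + K * math.exp(n)
        if spec.noise_sd > 0:
            for _ in range(100):
                cand = m + rng.normal(0.0, spec.noise_sd)
                if cand >= 0:
                    return cand
            raise GenerationError("noise keeps producing negative magnitudes")
        return m

    return _magnitude_table(spec, latent)


def generate_power_law(spec: SynthSpec) -> FCTable:
    """Magnitudes c*N**D with multiplicative log-normal noise."""
    if spec.model != "power_law":
        raise ValueError("spec.model must be 'power_law'")
    c = float(spec.params.get("c", 1.0))
    D = float(spec.params.get("D", 1.0))
    if c <= 0:
        raise GenerationError("power-law offset c must be positive")

    def latent(n: int, rng: np.random.Generator) -> float:
        m = c * n ** D
        if spec.noise_sd > 0:
            m *= math.exp(rng.normal(0.0, spec.noise_sd))
        return m

    return _magnitude_table(spec, latent)


def _lg_to_fc(lg: float) -> float:
    """Invert the signed log2 recoding: lg <= 0 -> 2**(-lg), lg > 0 -> -2**lg."""
    if lg <= 0:
        return 2.0 ** (-lg)
    return -(2.0 ** lg)


def _plant_tissue(
    n_genes: int,
    n_members: int,
    d: float,
    rng: np.random.Generator,
    tol: float,
    max_tries: int = 200,
) -> dict[str, float]:
    """LG values for one tissue with exactly the requested fractal members.

    Measured genes are G1..G{n_genes-1}; the housekeeping gene TBP sits at
    LG = 0.  Members G1..G{n_members} carry the arithmetic progression
    base + k*d with the base at the panel minimum (so the min-shift leaves
    the progression intact and its fractional parts unwrapped); remaining
    genes are drawn uniformly and the construction is re-drawn until the
    collinear detector reproduces the planted membership.
    """
    if not 0 <= n_members <= n_genes:
        raise ValueError("n_members must lie in [0, n_genes]")
    if n_members == n_genes and abs(d) * (n_genes - 1) == 0 and n_genes > 1:
        raise ValueError("degenerate common difference")
    measured = [f"G{i}" for i in range(1, n_genes)]
    member_genes = ([*measured[: n_members - 1], "TBP"]
                    if n_members == n_genes else measured[:n_members])
    free_genes = [g for g in measured if g not in member_genes]
    span = max(1.0, abs(d)) * max(n_members, 3)
    for _ in range(max_tries):
        lgs: dict[str, float] = {"TBP": 0.0}
        if n_members == n_genes:
            base = 0.0  # TBP anchors the progression at k = 0
            for k, g in enumerate(member_genes[:-1], start=1):
                lgs[g] = base + k * d
        else:
            base = -(1.0 + rng.uniform(0.1, 0.9))
            for k, g in enumerate(member_genes):  # first member sits at base
                lgs[g] = base + k * d
        for g in free_genes:
            lgs[g] = base + rng.uniform(0.3, span + 2.0)
        if min(lgs.values()) != base and n_members > 0:
            continue
        # verify via the actual detector on the implied portrait
        points = _portrait_from_lgs(lgs)
        sets = detect_collinear_sets(points, tol=tol)
        detected = (frozenset().union(*[s.genes for s in sets])
                    if sets else frozenset())
        expected = frozenset(member_genes) if n_members >= 3 else frozenset()
        if detected == expected:
            return lgs
    raise GenerationError(
        f"could not place {n_members} members among {n_genes} genes after "
        f"{max_tries} tries; widen the range or change the seed"
    )


def _portrait_from_lgs(lgs: Mapping[str, float]):
    from .transforms import PortraitPoint

    lo = min(lgs.values())
    pts = []
    for g, v in lgs.items():
        y = v - lo
        pts.append(PortraitPoint(gene=g, lg=v, y=y, x=y - math.floor(y)))
    return pts


def generate_portrait_panel(spec: SynthSpec) -> FCTable:
    """Panels with planted arithmetic progressions of LG values.

    ``params['n_members']`` may be one count for both tissues or a
    (breast, thigh) pair; ``params['common_difference']`` defaults to 1.1
    (fractional part 0.1, so an 8-member progression does not wrap).
    """
    if spec.model != "portrait_ap":
        raise ValueError("spec.model must be 'portrait_ap'")
    raw = spec.params.get("n_members", 0)
    n_b, n_t = (raw if isinstance(raw, (tuple, list)) else (raw, raw))
    d = float(spec.params.get("common_difference", 1.1))
    frac = d - math.floor(d)
    if frac == 0.0:
        raise GenerationError(
            "integer common difference stacks all progression points at one "
            "x; choose a non-integer value"
        )
    max_members = max(int(n_b), int(n_t))
    if max_members >= 2 and (max_members - 1) * frac >= 1.0:
        raise GenerationError(
            f"fractional part {frac:.3g} of the common difference wraps the "
            f"x-coordinate within {max_members} progression steps, breaking "
            "collinearity; choose frac(d) < 1/(n_members - 1)"
        )
    rng = np.random.default_rng(spec.seed)
    records = []
    for b in range(spec.n_breeds):
        breed = f"S{b + 1}"
        for tissue, n_members in (("breast", int(n_b)), ("thigh", int(n_t))):
            lgs = _plant_tissue(spec.n_genes, n_members, d, rng,
                                tol=DEFAULT_LINE_TOL)
            for gene, lg in lgs.items():
                if gene == "TBP" and lg == 0.0:
                    continue  # implied housekeeping reference
                records.append(FCRecord(breed, tissue, gene, _lg_to_fc(lg)))
    return FCTable(records)


def generate(spec: SynthSpec) -> FCTable:
    """Dispatch on ``spec.model``."""
    return {
        "rank_exponential": generate_rank_exponential,
        "power_law": generate_power_law,
        "portrait_ap": generate_portrait_panel,
    }[spec.model](spec)
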