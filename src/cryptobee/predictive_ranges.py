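"""Predicted measurement ranges and the range-plus-hair identification rule.

For each species x caste x ratio cell the study protocol extrapolates
beyond the measured specimens: bootstrap the cell mean (500 replicates),
then simulate 10,000 bees from a normal with that mean and the sample SD
and report the central 99% interval of the simulated distribution.  A
field identification rule then intersects a candidate bee's three ratios
with the predicted intervals and refines the surviving species set with
hair-colour rules (dark lower pleura is diagnostic for *B. perplexus*;
many black scutum hairs exclude it; yellow T3 hairs favour it).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .morphometrics import (
    RATIO_NAMES,
    SPECIES,
    HairProfile,
    RatioSet,
    SpecimenRecord,
    ratio_table,
)


def bootstrap_mean_sd(values: Sequence[float], B: int = 500,
                      seed: int = 0) -> tuple[float, float]:
    """Bootstrapped mean and plain sample SD of a measurement vector.

    The mean is the average of ``B`` bootstrap-replicate means; the SD is
    the ordinary ddof-1 sample SD of the original values.  The downstream
    simulation needs a population SD — simulating with the standard error
    instead would give predicted ranges narrower than the observed ones.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(x.size, size=(B, x.size))
    boot_mean = float(x[idx].mean(axis=1).mean())
    return boot_mean, float(x.std(ddof=1))


def simulate_quantile_range(mean: float, sd: float, n_sim: int = 10_000,
                            level: float = 0.99, seed: int = 0) -> tuple[float, float]:
    """Central ``level`` interval of ``n_sim`` normal(mean, sd) draws."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=n_sim)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RangeCell:
    n: int
    observed_min: float
    observed_max: float
    predicted_lo: float | None  # None when the cell has < 2 records
    predicted_hi: float | None


@dataclass(frozen=True)
class RangeTable:
    """Observed min–max and predicted 99% interval per (species, caste, ratio)."""

    cells: dict[tuple[str, str, str], RangeCell]

    def cell(self, species: str, caste: str, measurement: str) -> RangeCell:
        return self.cells[(species, caste, measurement)]

    def castes(self) -> set[str]:
        return {caste for (_, caste, _) in self.cells}

    def to_frame(self):
        import pandas as pd

        rows = [{"species": sp, "caste": ca, "measurement": m,
                 "n": c.n, "observed_min": c.observed_min, "observed_max": c.observed_max,
                 "predicted_lo": c.predicted_lo, "predicted_hi": c.predicted_hi}
                for (sp, ca, m), c in sorted(self.cells.items())]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame) -> "RangeTable":
        cells = {}
        for row in frame.itertuples(index=False):
            lo = None if row.predicted_lo is None or np.isnan(row.predicted_lo) else float(row.predicted_lo)
            hi = None if row.predicted_hi is None or np.isnan(row.predicted_hi) else float(row.predicted_hi)
            cells[(row.species, row.caste, row.measurement)] = RangeCell(
                int(row.n), float(row.observed_min), float(row.observed_max), lo, hi)
        return cls(cells)


def build_range_table(records: Sequence[SpecimenRecord], B: int = 500,
                      n_sim: int = 10_000, seed: int = 0) -> RangeTable:
    """Observed and predicted ranges for every species x caste x ratio cell.

    Cells with a single record get an observed range only (predicted
    bounds are None).  Each cell uses an independent stream derived from
    ``seed`` so the table is reproducible cell-by-cell.
    """
    df = ratio_table(records)
    cells: dict[tuple[str, str, str], RangeCell] = {}
    for (species, caste), grp in df.groupby(["species", "caste"], sort=True):
        for m in RATIO_NAMES:
            values = grp[m].to_numpy()
            key = zlib.crc32(f"{species}/{caste}/{m}".encode())
            cell_seed = np.random.SeedSequence([seed, key]).generate_state(1)[0]
            if values.size >= 2:
                mean, sd = bootstrap_mean_sd(values, B=B, seed=int(cell_seed))
                lo, hi = simulate_quantile_range(mean, sd, n_sim=n_sim,
                                                 seed=int(cell_seed) + 1)
            else:
                lo = hi = None
            cells[(species, caste, m)] = RangeCell(
                n=int(values.size),
                observed_min=float(values.min()),
                observed_max=float(values.max()),
                predicted_lo=lo, predicted_hi=hi,
            )
    return RangeTable(cells)


@dataclass(frozen=True)
class RangeID:
    """Outcome of the range-plus-hair identification rule.

    ``candidates`` is the surviving species set (possibly empty =
    ambiguous/none; *B. perplexus* listed first when the yellow-T3 rule
    marks it preferred); ``rationale`` records every rule firing.
    """

    candidates: tuple[str, ...]
    rationale: tuple[str, ...]


def classify_by_ranges(ratios: RatioSet, hair: HairProfile, caste: str,
                       table: RangeTable) -> RangeID:
    """Identify a bee from its three ratios and hair traits.

    Range filter first: a species survives only if all three ratios fall
    inside its predicted intervals for the bee's caste.  Hair rules then
    refine: dark (or dark-light) lower mesipisternum is diagnostic for
    *B. perplexus* and overrides the range filter; many black scutum
    hairs exclude *B. perplexus*; yellow hairs on T3 rank it first.
    """
    if caste not in table.castes():
        raise ValueError(f"range table has no {caste!r} rows")
    rationale: list[str] = []
    candidates: list[str] = []
    for species in SPECIES:
        hits = []
        ok = True
        for m in RATIO_NAMES:
            cell = table.cells.get((species, caste, m))
            if cell is None or cell.predicted_lo is None:
                ok = False
                hits.append(f"{m}: no predicted interval")
                break
            inside = cell.predicted_lo <= getattr(ratios, m) <= cell.predicted_hi
            hits.append(f"{m}={getattr(ratios, m):.3f} "
                        f"{'in' if inside else 'outside'} "
                        f"[{cell.predicted_lo:.3f}, {cell.predicted_hi:.3f}]")
            ok = ok and inside
        rationale.append(f"{species}: {'kept' if ok else 'excluded'} ({'; '.join(hits)})")
        if ok:
            candidates.append(species)

    if hair.mesipisternum in ("dark", "dark-light"):
        rationale.append(
            f"mesipisternum={hair.mesipisternum}: dark lower pleura is diagnostic "
            "for perplexus — candidate set forced to {perplexus}")
        candidates = ["perplexus"]
    elif hair.scutum_black == "many" and "perplexus" in candidates:
        rationale.append("scutum_black=many: perplexus dropped (its scutum is "
                         "all light or has only a few black hairs)")
        candidates = [s for s in candidates if s != "perplexus"]

    if hair.t3_yellow and "perplexus" in candidates and len(candidates) > 1:
        rationale.append("t3_yellow=true: perplexus preferred (light-form "
                         "perplexus often shows yellow T3 hairs)")
        candidates = ["perplexus"] + [s for s in candidates if s != "perplexus"]

    return RangeID(candidates=tuple(candidates), rationale=tuple(rationale))
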