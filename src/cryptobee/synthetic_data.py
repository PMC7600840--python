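"""Synthetic specimen, replicate-measurement and barcode generators.

The study's raw measurement table is unpublished ("available upon
request"), so every downstream analysis here is exercised on synthetic
data calibrated to the published summary statistics:

* per species × caste ratio means from the fitted-model mean table,
* population SDs recovered from the published predicted 99% ranges
  (central normal interval: ``sd = (hi - lo) / (2 * z_0.995)``),
* sample sizes per cell (19/27/35 workers, 3/22/9 queens; 115 total),
* pooled inter-ratio correlations (MR1–MR3 0.66, MR1–MRL 0.75,
  MR3–MRL 0.77),
* hair-trait category spans per cell,
* a toy COI barcode set reproducing the published haplotype structure
  (monomorphic *B. sandersoni* and *B. vagans*; two *B. perplexus*
  haplotypes one base pair apart) and pairwise percent identities.

All generators take an integer seed and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .morphometrics import HairProfile, RatioSet, SpecimenRecord

RATIOS = ("mr1", "mr3", "mrl")

#: z such that the central 99% normal interval is mean +- z * sd
Z_995 = 2.5758293035489004

#: published pooled Pearson correlations among (mr1, mr3, mrl)
POOLED_CORRELATIONS = {("mr1", "mr3"): 0.66, ("mr1", "mrl"): 0.75, ("mr3", "mrl"): 0.77}

# Calibration inputs: per species x caste -> n, ratio means, predicted
# 99% intervals, and hair-trait category spans.  Mesipisternum entries
# are single categories; scutum/T5 entries are equiprobable spans.
_CALIBRATION: dict[tuple[str, str], dict] = {
    ("perplexus", "worker"): dict(
        n=19, mean=dict(mr1=1.40, mr3=1.63, mrl=0.80),
        q99=dict(mr1=(1.24, 1.56), mr3=(1.37, 1.86), mrl=(0.73, 0.85)),
        mesipisternum="dark-light", scutum_black=("none", "few"), t5_yellow=("none", "few"),
    ),
    ("sandersoni", "worker"): dict(
        n=27, mean=dict(mr1=1.21, mr3=1.49, mrl=0.75),
        q99=dict(mr1=(1.00, 1.42), mr3=(1.30, 1.70), mrl=(0.64, 0.84)),
        mesipisternum="light", scutum_black=("few", "many"), t5_yellow=("none", "few", "many"),
    ),
    ("vagans", "worker"): dict(
        n=35, mean=dict(mr1=1.46, mr3=1.83, mrl=0.92),
        q99=dict(mr1=(1.30, 1.62), mr3=(1.57, 2.08), mrl=(0.86, 0.99)),
        mesipisternum="light", scutum_black=("many",), t5_yellow=("none", "few", "many"),
    ),
    ("perplexus", "queen"): dict(
        n=3, mean=dict(mr1=1.38, mr3=1.79, mrl=0.82),
        q99=dict(mr1=(1.35, 1.40), mr3=(1.54, 2.20), mrl=(0.78, 0.87)),
        mesipisternum="dark", scutum_black=("none", "few"), t5_yellow=("none",),
    ),
    ("sandersoni", "queen"): dict(
        n=22, mean=dict(mr1=1.19, mr3=1.66, mrl=0.77),
        q99=dict(mr1=(1.07, 1.31), mr3=(1.48, 1.81), mrl=(0.68, 0.85)),
        mesipisternum="light", scutum_black=("few", "many"), t5_yellow=("none", "few", "many"),
    ),
    ("vagans", "queen"): dict(
        n=9, mean=dict(mr1=1.44, mr3=2.00, mrl=0.94),
        q99=dict(mr1=(1.33, 1.57), mr3=(1.80, 2.22), mrl=(0.86, 0.99)),
        mesipisternum="light", scutum_black=("many",), t5_yellow=("none", "few", "many"),
    ),
}

#: fraction of field identifications that agree with DNA in the study data
VISUAL_AGREEMENT_RATE = 0.704

#: probability that a light-form *B. perplexus* shows yellow hairs on T3
T3_YELLOW_RATE = 0.7


def nearest_psd(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping),
    then restore the unit diagonal."""
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    out = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def pooled_correlation_matrix() -> np.ndarray:
    """3x3 correlation matrix among (mr1, mr3, mrl), PSD-projected if needed."""
    corr = np.eye(3)
    idx = {name: i for i, name in enumerate(RATIOS)}
    for (a, b), r in POOLED_CORRELATIONS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return nearest_psd(corr)


@dataclass(frozen=True)
class SpeciesCasteParams:
    """Calibrated generating distribution for one species x caste cell."""

    species: str
    caste: str
    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    corr: np.ndarray = field(default_factory=pooled_correlation_matrix)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(self.sd[r] < 0 for r in RATIOS):
            raise ValueError("sd must be non-negative")
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ValueError("corr must be symmetric 3x3 with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("corr is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        s = np.array([self.sd[r] for r in RATIOS])
        return np.asarray(self.corr) * np.outer(s, s)

    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean[r] for r in RATIOS])


@dataclass(frozen=True)
class ObserverNoiseModel:
    """Measurement-error model on the ratio scale.

    ``within_sd`` is the replicate-to-replicate SD within one observer;
    ``between_bias_sd`` the SD of a persistent per-observer offset.  The
    defaults are chosen so that, at the pooled between-bee SD of the
    calibrated 115-bee table (~0.12 on MR1), within-observer replicate
    correlations land near the published ~0.95 and replicate SDs stay
    inside the published 0–0.11 range.
    """

    within_sd: float = 0.03
    between_bias_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.within_sd < 0 or self.between_bias_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def sd_from_interval(lo: float, hi: float) -> float:
    """Population SD implied by a central 99% normal interval (lo, hi)."""
    if hi < lo:
        raise ValueError("interval upper bound below lower bound")
    return (hi - lo) / (2.0 * Z_995)


def default_params() -> list[SpeciesCasteParams]:
    """The six calibrated species x caste parameter sets (115 bees total)."""
    corr = pooled_correlation_matrix()
    out = []
    for (species, caste), cell in _CALIBRATION.items():
        out.append(SpeciesCasteParams(
            species=species, caste=caste, n=cell["n"], mean=dict(cell["mean"]),
            sd={r: sd_from_interval(*cell["q99"][r]) for r in RATIOS},
            corr=corr,
        ))
    return out


def _draw_hair(rng: np.random.Generator, species: str, caste: str) -> HairProfile:
    cell = _CALIBRATION[(species, caste)]
    mes = cell["mesipisternum"]
    scutum = cell["scutum_black"][rng.integers(len(cell["scutum_black"]))]
    t5 = cell["t5_yellow"][rng.integers(len(cell["t5_yellow"]))]
    t3 = bool(species == "perplexus" and mes == "light"
              and rng.random() < T3_YELLOW_RATE)
    return HairProfile(mesipisternum=mes, scutum_black=scutum, t5_yellow=t5, t3_yellow=t3)


def _draw_visual(rng: np.random.Generator, species: str) -> str:
    if rng.random() < VISUAL_AGREEMENT_RATE:
        return species
    others = [s for s in ("sandersoni", "vagans", "perplexus") if s != species]
    return others[rng.integers(2)]


def simulate_specimens(
    params: Sequence[SpeciesCasteParams] | None = None,
    seed: int = 0,
    id_prefix: str = "SIM",
) -> list[SpecimenRecord]:
    """Draw one synthetic specimen table.

    Per cell, ``n`` (mr1, mr3, mrl) triples come from the multivariate
    normal with the cell's mean/SD and the pooled correlation matrix.
    Raw reticle measurements are back-filled consistently with the drawn
    ratios by anchoring malar_width at 1 reticle unit (only the ratios
    are identifiable).  Regions are assigned 50/50; hair traits follow
    the per-cell category spans; a visual label is simulated at the
    published field-identification agreement rate.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    records: list[SpecimenRecord] = []
    counter = 0
    for p in params:
        cov = p.covariance()
        mean = p.mean_vector()
        draws = rng.multivariate_normal(mean, cov, size=p.n, method="cholesky")
        bad = ~(draws > 0).all(axis=1)
        while bad.any():  # astronomically rare at calibrated SDs
            draws[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()),
                                                 method="cholesky")
            bad = ~(draws > 0).all(axis=1)
        for mr1, mr3, mrl in draws:
            counter += 1
            malar_length = mrl  # width anchored at 1 reticle unit
            records.append(SpecimenRecord(
                id=f"{id_prefix}{counter:04d}",
                species_dna=p.species,
                species_visual=_draw_visual(rng, p.species),
                caste=p.caste,
                region=("Midwest", "Northeast")[rng.integers(2)],
                observer="Obs1",
                malar_length=malar_length,
                malar_width=1.0,
                flag1_length=malar_length / mr1,
                flag3_length=malar_length / mr3,
                hair=_draw_hair(rng, p.species, p.caste),
            ))
    return records


def simulate_observer_replicates(
    records: Sequence[SpecimenRecord],
    noise: ObserverNoiseModel | None = None,
    n_observers: int = 2,
    n_reps: int = 2,
    seed: int = 0,
):
    """Replicate-measurement table: true ratio + observer bias + replicate noise.

    Returns a tidy DataFrame with one row per specimen x observer x rep
    and columns ``specimen_id, observer, rep, mr1, mr3, mrl``.
    """
    import pandas as pd

    from .morphometrics import compute_ratios

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise is None:
        noise = ObserverNoiseModel()
    rng = np.random.default_rng(seed)
    biases = rng.normal(0.0, noise.between_bias_sd, size=(n_observers, len(RATIOS)))
    rows = []
    import warnings as _w
    for rec in records:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            true = compute_ratios(rec)
        t = np.array([true.mr1, true.mr3, true.mrl])
        for obs in range(n_observers):
            for rep in range(n_reps):
                val = t + biases[obs] + rng.normal(0.0, noise.within_sd, size=3)
                rows.append({
                    "specimen_id": rec.id,
                    "observer": f"Obs{obs + 1}",
                    "rep": rep + 1,
                    "mr1": val[0], "mr3": val[1], "mrl": val[2],
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BarcodeSimSpec:
    """Target structure for the toy COI barcode set.

    ``divergence`` maps unordered species pairs to exact Hamming
    distances between species templates; ``haplotype_split`` optionally
    gives (species, frequency) for a within-species variant one base
    pair away from that species' template.
    """

    length: int = 140
    divergence: Mapping[frozenset, int] = field(default_factory=lambda: {
        frozenset({"sandersoni", "vagans"}): 6,
        frozenset({"sandersoni", "perplexus"}): 8,
        frozenset({"vagans", "perplexus"}): 8,
    })
    haplotype_split: tuple[str, float] | None = ("perplexus", 0.5)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if any(k < 0 for k in self.divergence.values()):
            raise ValueError("divergences must be non-negative")


_BASES = np.array(list("ACGT"))

#: specimen counts per species in the sequenced study sample
DEFAULT_BARCODE_COUNTS = {"sandersoni": 49, "vagans": 44, "perplexus": 22}


def _species_templates(spec: BarcodeSimSpec, rng: np.random.Generator) -> dict[str, str]:
    """Build three equal-length templates with exact pairwise Hamming distances.

    Decomposes the distance triple into site classes: x sites where only
    vagans differs from sandersoni, y where only perplexus differs, w
    where vagans and perplexus share a non-sandersoni base, z where all
    three differ.  Solvable iff d_sv + d_sp - d_vp >= 0 and the class
    counts are non-negative and fit in the length.
    """
    d_sv = spec.divergence[frozenset({"sandersoni", "vagans"})]
    d_sp = spec.divergence[frozenset({"sandersoni", "perplexus"})]
    d_vp = spec.divergence[frozenset({"vagans", "perplexus"})]
    excess = d_sv + d_sp - d_vp
    if excess < 0:
        raise ValueError("divergence triple violates the triangle inequality")
    w, z = divmod(excess, 2)
    x = d_sv - z - w
    y = d_sp - z - w
    if x < 0 or y < 0:
        raise ValueError(f"divergence triple {d_sv, d_sp, d_vp} is not realisable")
    total = x + y + z + w
    if total > spec.length:
        raise ValueError("divergences exceed sequence length")

    base = rng.integers(4, size=spec.length)
    sites = rng.choice(spec.length, size=total, replace=False)
    sx, sy, sz, sw = np.split(sites, np.cumsum([x, y, z])[:3])
    sand, vag, perp = base.copy(), base.copy(), base.copy()
    for s in sx:
        vag[s] = (base[s] + 1) % 4
    for s in sy:
        perp[s] = (base[s] + 1) % 4
    for s in sw:
        vag[s] = perp[s] = (base[s] + 1) % 4
    for s in sz:
        vag[s] = (base[s] + 1) % 4
        perp[s] = (base[s] + 2) % 4
    used = set(sites.tolist())
    return (
        {"sandersoni": "".join(_BASES[sand]),
         "vagans": "".join(_BASES[vag]),
         "perplexus": "".join(_BASES[perp])},
        used,
    )


def simulate_barcode_set(
    spec: BarcodeSimSpec | None = None,
    counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Generate (id, species, sequence) triples with the target structure.

    Within-species sequences are identical except for the optional
    haplotype split, which mutates one extra site (outside the
    divergence-defining sites) in a ``frequency`` fraction of that
    species' individuals — reproducing the published picture of two
    monomorphic species plus a two-haplotype *B. perplexus*.
    """
    if spec is None:
        spec = BarcodeSimSpec()
    if counts is None:
        counts = dict(DEFAULT_BARCODE_COUNTS)
    rng = np.random.default_rng(seed)
    templates, used = _species_templates(spec, rng)

    variant: dict[str, str] = {}
    split_species, split_freq = (None, 0.0)
    if spec.haplotype_split is not None:
        split_species, split_freq = spec.haplotype_split
        others = [s for s in templates if s != split_species]
        tpl = list(templates[split_species])
        # Prefer a site where the split species already differs from both
        # other templates: mutating it to a fresh base keeps all
        # between-species distances exact while separating the two
        # within-species haplotypes by one base pair.
        candidates = [
            i for i in range(spec.length)
            if all(tpl[i] != templates[o][i] for o in others)
        ]
        if candidates:
            site = int(rng.choice(candidates))
            taken = {tpl[site]} | {templates[o][site] for o in others}
            tpl[site] = next(b for b in "ACGT" if b not in taken)
        else:  # fallback: a fresh site (shifts between-species counts by one)
            free = [i for i in range(spec.length) if i not in used]
            if not free:
                raise ValueError("no free site left for the haplotype split")
            site = int(rng.choice(free))
            tpl[site] = _BASES[(int(np.where(_BASES == tpl[site])[0][0]) + 1) % 4]
        variant[split_species] = "".join(tpl)

    out: list[tuple[str, str, str]] = []
    i = 0
    for species in ("sandersoni", "vagans", "perplexus"):
        n = counts.get(species, 0)
        n_var = round(n * split_freq) if species == split_species else 0
        for j in range(n):
            i += 1
            seq = variant[species] if j < n_var else templates[species]
            out.append((f"BC{i:04d}", species, seq))
    return out
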