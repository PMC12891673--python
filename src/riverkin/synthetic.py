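"""Synthetic landscapes, pedigrees and noisy fecal-sample genotypes.

This module generates data with the statistical structure the downstream
pipeline assumes, together with the ground truth needed for recovery tests:

* a rectangular study area divided into bands by sub-parallel west-east
  rivers (sinusoidal meanders on parallel baselines);
* pedigreed families (two parents drawn from Hardy-Weinberg, offspring by
  Mendelian transmission) whose parent-offspring and full-sib pairs are the
  true first-order dyads;
* sex-specific dispersal: every offspring (and each father) settles at a
  distance drawn from its sex's kernel in a uniformly random direction from
  the mother, with a *crossing aversion* implemented by rejection-resampling
  of proposals whose settlement segment crosses a river;
* noisy replicated sampling: 1..k fecal samples per individual with
  per-allele genotyping error, per-locus missingness and coordinate jitter.

Distance kernels default to log-normal with a male median of 45 km and a
female median of 18 km, a heavy-tailed choice consistent with field reports
of male mean dispersal more than twice the female mean and standard
deviations of the same order as the means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely.geometry import LineString

from .geometry import RiverSet, rivers_crossed
from .records import MISSING, Panel

__all__ = [
    "simulate_world",
    "LandscapeSpec",
    "DistanceKernel",
    "DispersalKernelSpec",
    "TrueIndividual",
    "DispersalEvent",
    "SyntheticTruth",
    "generate_landscape",
    "generate_population",
    "disperse_and_settle",
    "sample_genotypes",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Rectangular study area crossed by sub-parallel west-east rivers.

    All lengths in metres. ``reference_azimuth_deg`` is the compass azimuth
    of the line orthogonal to the mean river course; with west-east rivers
    that line runs south-north, azimuth 0.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 250_000.0, 200_000.0)
    n_rivers: int = 3
    river_spacing: float = 50_000.0
    meander_amplitude: float = 8_000.0
    meander_wavelength: float = 70_000.0
    reference_azimuth_deg: float = 0.0

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        if self.n_rivers < 0:
            raise ValueError("n_rivers must be >= 0")
        if self.n_rivers > 0:
            if self.river_spacing <= 0:
                raise ValueError("river_spacing must be positive")
            if self.river_spacing * (self.n_rivers + 1) > (ymax - ymin) + 1e-9:
                raise ValueError("rivers with this spacing do not fit in the extent")
            if self.meander_amplitude < 0 or (
                self.meander_amplitude > 0 and self.meander_wavelength <= 0
            ):
                raise ValueError("bad meander parameters")
            if 2 * self.meander_amplitude >= self.river_spacing:
                raise ValueError("meander amplitude too large: rivers could touch")


@dataclass(frozen=True)
class DistanceKernel:
    """Parametric dispersal-distance distribution (km), non-negative support.

    families: "lognormal" (params: median_km, sigma of log) and
    "constant" (params: distance_km).
    """

    family: str = "lognormal"
    median_km: float = 20.0
    sigma: float = 0.7
    distance_km: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            return rng.lognormal(math.log(self.median_km), self.sigma, size=n)
        if self.family == "constant":
            return np.full(n, float(self.distance_km))
        raise ValueError(f"unknown kernel family {self.family!r}")


@dataclass(frozen=True)
class DispersalKernelSpec:
    male: DistanceKernel = DistanceKernel("lognormal", median_km=45.0, sigma=0.67)
    female: DistanceKernel = DistanceKernel("lognormal", median_km=18.0, sigma=0.69)
    female_crossing_aversion: float = 0.0
    male_crossing_aversion: float = 0.0

    def validate(self) -> None:
        for a in (self.female_crossing_aversion, self.male_crossing_aversion):
            if not 0.0 <= a <= 1.0:
                raise ValueError("crossing aversion must be in [0, 1]")

    def kernel_for(self, sex: str) -> DistanceKernel:
        return self.male if sex == "M" else self.female

    def aversion_for(self, sex: str) -> float:
        return self.male_crossing_aversion if sex == "M" else self.female_crossing_aversion


@dataclass
class TrueIndividual:
    individual_id: str
    sex: str  # "M" | "F"
    family: int
    role: str  # "mother" | "father" | "offspring"
    genotype: np.ndarray  # int8 codes


@dataclass
class DispersalEvent:
    individual_id: str
    sex: str
    origin: tuple[float, float]
    settlement: tuple[float, float]
    distance_km: float
    n_rivers_crossed: int


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic world."""

    panel: Panel
    individuals: dict[str, TrueIndividual]
    first_order_pairs: list[tuple[str, str, str]]  # (id_a, id_b, "PO"|"FS")
    allele_freqs: np.ndarray  # frequency of the a1 allele per locus
    seed: int
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)
    dispersals: list[DispersalEvent] = field(default_factory=list)
    kernel: DispersalKernelSpec | None = None

    def ids_by_sex(self, sex: str) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.sex == sex]


def generate_landscape(spec: LandscapeSpec, seed: int) -> RiverSet:
    """Build the river set: sinusoidal perturbations of parallel baselines.

    Rivers span the full west-east width, are ordered south to north, and are
    re-verified simple and pairwise non-intersecting rather than assumed so.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = spec.extent
    height = ymax - ymin
    # center the band structure vertically
    y0 = ymin + (height - spec.river_spacing * (spec.n_rivers + 1)) / 2.0
    names, lines = [], []
    n_vertices = max(50, int(math.ceil((xmax - xmin) / max(spec.meander_wavelength, 1.0) * 24)))
    xs = np.linspace(xmin, xmax, n_vertices)
    for i in range(spec.n_rivers):
        base = y0 + spec.river_spacing * (i + 1)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        if spec.meander_amplitude > 0:
            ys = base + spec.meander_amplitude * np.sin(
                2.0 * math.pi * xs / spec.meander_wavelength + phase
            )
        else:
            ys = np.full_like(xs, base)
        names.append(f"River {i + 1}")
        lines.append(LineString(np.column_stack([xs, ys])))
    for i, li in enumerate(lines):
        if not li.is_simple:
            raise ValueError(f"generated river {names[i]} is self-intersecting")
        for j in range(i + 1, len(lines)):
            if li.intersects(lines[j]):
                raise ValueError(f"rivers {names[i]} and {names[j]} intersect")
    return RiverSet(
        names=names,
        lines=lines,
        reference_azimuth_deg=spec.reference_azimuth_deg,
        extent=spec.extent,
    )


def _resolve_count(dist, rng: np.random.Generator) -> int:
    """Draw one count from an int constant or a callable(rng) -> int."""
    if isinstance(dist, int):
        return dist
    return int(dist(rng))


def _gamete(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele (0 or 1 copies of a1) per locus."""
    out = codes // 2  # 0 -> 0, 2 -> 1
    het = codes == 1
    out = out.copy()
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    return out


def generate_population(
    n_families: int,
    offspring_per_family: int | Callable[[np.random.Generator], int],
    n_loci: int,
    allele_freqs: np.ndarray | float,
    seed: int,
    panel: Panel | None = None,
) -> SyntheticTruth:
    """Pedigreed families with Hardy-Weinberg parents and Mendelian offspring.

    ``allele_freqs`` is the frequency of the a1 allele per locus, all in the
    open interval (0, 1); a scalar is broadcast. Offspring sexes are
    Bernoulli(0.5). Every parent-offspring and full-sib pair is recorded
    exactly once in ``first_order_pairs``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), (n_loci,)).copy()
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    panel = panel or Panel.default(n_loci)
    if panel.n_loci != n_loci:
        raise ValueError("panel size does not match n_loci")
    rng = np.random.default_rng(seed)

    individuals: dict[str, TrueIndividual] = {}
    pairs: list[tuple[str, str, str]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    def hw_genotype() -> np.ndarray:
        return (
            (rng.random(n_loci) < freqs).astype(np.int8)
            + (rng.random(n_loci) < freqs).astype(np.int8)
        )

    for fam in range(n_families):
        mid, fid = new_id(), new_id()
        gm, gf = hw_genotype(), hw_genotype()
        individuals[mid] = TrueIndividual(mid, "F", fam, "mother", gm)
        individuals[fid] = TrueIndividual(fid, "M", fam, "father", gf)
        n_off = _resolve_count(offspring_per_family, rng)
        kids = []
        for _ in range(n_off):
            kid = new_id()
            gk = (_gamete(gm, rng) + _gamete(gf, rng)).astype(np.int8)
            sex = "M" if rng.random() < 0.5 else "F"
            individuals[kid] = TrueIndividual(kid, sex, fam, "offspring", gk)
            pairs.append((mid, kid, "PO"))
            pairs.append((fid, kid, "PO"))
            for sib in kids:
                pairs.append((sib, kid, "FS"))
            kids.append(kid)
    return SyntheticTruth(
        panel=panel,
        individuals=individuals,
        first_order_pairs=pairs,
        allele_freqs=freqs,
        seed=seed,
    )


def _settle_from(
    origin: tuple[float, float],
    sex: str,
    kernel: DispersalKernelSpec,
    rivers: RiverSet,
    extent: tuple[float, float, float, float],
    rng: np.random.Generator,
    max_retries: int,
) -> tuple[tuple[float, float], float, int]:
    """Propose settlement points until one is inside the extent and survives
    the crossing-aversion rejection step. Returns (point, distance_km, crossings)."""
    xmin, ymin, xmax, ymax = extent
    aversion = kernel.aversion_for(sex)
    k = kernel.kernel_for(sex)
    for _ in range(max_retries):
        d_km = float(k.draw(rng, 1)[0])
        theta = rng.uniform(0.0, 2.0 * math.pi)
        prop = (
            origin[0] + 1000.0 * d_km * math.cos(theta),
            origin[1] + 1000.0 * d_km * math.sin(theta),
        )
        if not (xmin <= prop[0] <= xmax and ymin <= prop[1] <= ymax):
            continue
        if d_km == 0.0:
            return prop, 0.0, 0
        n_cross = rivers_crossed(origin, prop, rivers) if len(rivers) else 0
        if n_cross >= 1 and rng.random() < aversion:
            continue
        return prop, d_km, n_cross
    raise RuntimeError(
        f"settlement failed after {max_retries} proposals "
        "(aversion/geometry may make settlement impossible)"
    )


def disperse_and_settle(
    truth: SyntheticTruth,
    rivers: RiverSet,
    kernel: DispersalKernelSpec,
    seed: int,
    max_retries: int = 10_000,
) -> SyntheticTruth:
    """Place every individual in the landscape and log true crossing events.

    Mothers are placed uniformly in the extent. Fathers and offspring settle
    from the mother's position at a kernel-drawn distance in a uniformly
    random direction; a proposal whose straight settlement segment crosses at
    least one river is rejected with probability equal to the sex's crossing
    aversion (and re-drawn), so the realized distance distribution is not
    truncated by the barrier. Proposals outside the extent are always
    re-drawn. Fills ``truth.coordinates`` and ``truth.dispersals`` in place.
    """
    kernel.validate()
    if rivers.extent is None:
        raise ValueError("RiverSet must carry the landscape extent")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = rivers.extent
    fams: dict[int, dict[str, list[str]]] = {}
    for iid, ind in truth.individuals.items():
        fams.setdefault(ind.family, {"mother": [], "father": [], "offspring": []})[
            ind.role
        ].append(iid)
    for fam in sorted(fams):
        roles = fams[fam]
        (mid,) = roles["mother"]
        mpos = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        truth.coordinates[mid] = mpos
        for iid in roles["father"] + roles["offspring"]:
            sex = truth.individuals[iid].sex
            pos, d_km, n_cross = _settle_from(
                mpos, sex, kernel, rivers, rivers.extent, rng, max_retries
            )
            truth.coordinates[iid] = pos
            truth.dispersals.append(
                DispersalEvent(iid, sex, mpos, pos, d_km, n_cross)
            )
    truth.kernel = kernel
    return truth


def sample_genotypes(
    truth: SyntheticTruth,
    samples_per_individual: int | Callable[[np.random.Generator], int] = 1,
    error_rate: float = 0.005,
    missing_rate: float = 0.05,
    jitter_sd: float = 2_000.0,
    seed: int = 0,
):
    """Emit noisy replicated fecal-sample records for every individual.

    Per sample: isotropic Gaussian coordinate jitter (sd in metres), per-locus
    missingness, and independent per-allele substitution errors (an allele is
    replaced by the locus's other allele with probability ``error_rate``).
    Sex-marker calls are consistent with the true sex: Y markers amplify only
    in males, X markers in everyone.
    """
    from .records import SampleRecord

    if not truth.coordinates:
        raise ValueError("truth has no coordinates; run disperse_and_settle first")
    rng = np.random.default_rng(seed)
    panel = truth.panel
    n_loci = panel.n_loci
    records = []
    for iid in sorted(truth.individuals):
        ind = truth.individuals[iid]
        x0, y0 = truth.coordinates[iid]
        n_samp = max(1, _resolve_count(samples_per_individual, rng))
        for s in range(n_samp):
            g = ind.genotype.astype(np.int64).copy()
            if error_rate > 0:
                # each of the two alleles flips to the other with prob error_rate
                n_a1 = g.copy()
                n_a0 = 2 - g
                flip_a1 = rng.binomial(n_a1, error_rate)
                flip_a0 = rng.binomial(n_a0, error_rate)
                g = n_a1 - flip_a1 + flip_a0
            if missing_rate > 0:
                g[rng.random(n_loci) < missing_rate] = MISSING
            jx, jy = rng.normal(0.0, jitter_sd, 2) if jitter_sd > 0 else (0.0, 0.0)
            records.append(
                SampleRecord(
                    sample_id=f"{iid}_s{s + 1}",
                    x=x0 + jx,
                    y=y0 + jy,
                    genotype=g.astype(np.int8),
                    y_calls=np.full(panel.n_y_markers, ind.sex == "M"),
                    x_calls=np.ones(panel.n_x_markers, dtype=bool),
                )
            )
    return records


def simulate_world(
    seed: int,
    n_families: int = 150,
    mean_offspring: float = 2.0,
    n_loci: int = 85,
    landscape: LandscapeSpec | None = None,
    kernel: DispersalKernelSpec | None = None,
    mean_extra_samples: float = 0.9,
    error_rate: float = 0.005,
    missing_rate: float = 0.05,
    jitter_sd: float = 2_000.0,
    freq_low: float = 0.3,
    freq_high: float = 0.7,
):
    """One full synthetic study: landscape, pedigree, dispersal, samples.

    Returns (records, rivers, truth). Family sizes are 1 + Poisson
    (mean_offspring - 1); samples per individual are 1 + Poisson
    (mean_extra_samples). Sub-seeds for each stage are derived from ``seed``.
    """
    landscape = landscape or LandscapeSpec()
    kernel = kernel or DispersalKernelSpec()
    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    freq_rng = np.random.default_rng(sub[0])
    freqs = freq_rng.uniform(freq_low, freq_high, n_loci)
    rivers = generate_landscape(landscape, seed=sub[1])
    lam = max(0.0, mean_offspring - 1.0)
    truth = generate_population(
        n_families=n_families,
        offspring_per_family=lambda rng: 1 + rng.poisson(lam),
        n_loci=n_loci,
        allele_freqs=freqs,
        seed=sub[2],
    )
    disperse_and_settle(truth, rivers, kernel, seed=sub[3])
    records = sample_genotypes(
        truth,
        samples_per_individual=lambda rng: 1 + rng.poisson(mean_extra_samples),
        error_rate=error_rate,
        missing_rate=missing_rate,
        jitter_sd=jitter_sd,
        seed=sub[4],
    )
    return records, rivers, truth
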