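"""Seeded generators for every input the genotyping pipeline consumes.

The generators emulate the statistical structure of a two-cohort SNP study of
the HLA-E promoter variant rs76971248 (NT-26 G>T): diploid cohorts sampled
under Hardy-Weinberg proportions at the study's allele frequencies (T-allele
0.0416 in leukemia patients, 0.0929 in healthy donors; n = 228 / 226),
IUPAC consensus sequences built from allele pairs with optional per-position
base-call noise, bivariate endpoint-fluorescence clusters per genotype, and
sigmoid melt curves (the heterozygote melts as an equal mixture of the
homoduplex and a lower-Tm heteroduplex transition).

All randomness flows through one explicit seed or Generator argument; there
is no global RNG state, and a fixed seed reproduces outputs exactly.

A packaged synthetic toy reference database (four alleles over a 400-nt
amplicon, NT-26 at column 133) stands in for the real allele catalogue; only
one allele carries the NT-26 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .allele_db import AlleleDB, load_allele_db
from .errors import InputError
from .genotype import GENOTYPES, GG, GT, TT
from .sbt import ConsensusSeq, IUPAC_CODES, expected_consensus
from .signals import EndpointSignal, MeltCurve

# Study conditions: cohort sizes and T-allele frequencies.
DEFAULT_CASE_N = 228
DEFAULT_CONTROL_N = 226
DEFAULT_CASE_T_FREQ = 0.0416
DEFAULT_CONTROL_T_FREQ = 0.0929

#: Endpoint cluster centres (fx, fy) per genotype, arbitrary fluorescence
#: units. G/G lights the wild-type probe channel, T/T the mutant channel,
#: heterozygotes both.
DEFAULT_CENTROIDS: dict[str, tuple[float, float]] = {
    GG: (30.0, 3.0),
    GT: (18.0, 18.0),
    TT: (3.0, 30.0),
}
DEFAULT_ENDPOINT_NOISE_SD = 1.0

#: Melt-transition mixture per genotype: (weight, Tm degC) components.
#: Homozygotes melt as a single duplex; the heterozygote as an equal mix of
#: the G homoduplex and a destabilized heteroduplex ~3 degC lower.
DEFAULT_TM_COMPONENTS: dict[str, tuple[tuple[float, float], ...]] = {
    GG: ((1.0, 84.6),),
    TT: ((1.0, 83.4),),
    GT: ((0.5, 84.6), (0.5, 81.8)),
}
DEFAULT_TRANSITION_WIDTH = 0.7  # degC, logistic scale of the melt transition
DEFAULT_MELT_NOISE_SD = 0.15  # raw fluorescence units (amplitude 40)
DEFAULT_MELT_GRID = np.arange(65.0, 92.01, 0.2)
DEFAULT_PRE_WINDOW = (68.0, 72.0)
DEFAULT_POST_WINDOW = (89.0, 92.0)

_IUPAC_LIST = sorted(IUPAC_CODES)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def toy_db() -> AlleleDB:
    """Load the packaged synthetic toy allele database with the NT-26 site."""
    data = resources.files("hlae_typing") / "data"
    return load_allele_db(
        str(data / "toy_alleles_synthetic.fasta"), str(data / "sites.yaml")
    )


@dataclass(frozen=True)
class CohortSpec:
    """Simulation spec for one cohort: size, T-allele frequency, HWE flag."""

    n: int
    t_freq: float
    hwe: bool = True
    label: str = "cohort"

    def __post_init__(self) -> None:
        if not 0 <= self.t_freq <= 1:
            raise InputError(f"t_freq must be in [0, 1], got {self.t_freq}")
        if self.n < 0:
            raise InputError("cohort size must be non-negative")


@dataclass
class SimulatedSample:
    """Ground truth plus generated records for one simulated individual."""

    sample_id: str
    genotype: str
    allele_pair: tuple[str, str] | None = None
    consensus: ConsensusSeq | None = None
    endpoint: EndpointSignal | None = None
    melt_wells: list[MeltCurve] = field(default_factory=list)


def simulate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> list[str]:
    """Draw genotypes for one cohort.

    Under HWE, the two alleles of each individual are independent Bernoulli
    draws at the T frequency, giving genotype probabilities (p^2, 2pq, q^2).
    With ``hwe=False`` the cohort is maximally disequilibrated: only
    homozygotes, G/G with probability p and T/T with probability q.
    """
    rng = _rng(seed)
    q = spec.t_freq
    if spec.hwe:
        n_t_alleles = rng.binomial(2, q, size=spec.n)
        return [(GG, GT, TT)[k] for k in n_t_alleles]
    is_tt = rng.random(spec.n) < q
    return [TT if t else GG for t in is_tt]


def _alleles_by_site_base(db: AlleleDB, site_label: str) -> tuple[list[str], list[str]]:
    site = db.site(site_label)
    g_like = [a for a in db.allele_ids if db.record(a).region_seq[site.index] == site.ref_base]
    t_like = [a for a in db.allele_ids if db.record(a).region_seq[site.index] == site.alt_base]
    return g_like, t_like


def genotype_to_consensus(
    genotype: str,
    db: AlleleDB,
    site_label: str = "NT-26",
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "sim",
) -> tuple[ConsensusSeq, tuple[str, str]]:
    """Build an IUPAC consensus for a genotype by drawing a consistent pair.

    A uniformly drawn allele pair matching the site genotype is superposed
    into its expected consensus; each position is then independently replaced
    by a random *different* IUPAC code with probability ``error_rate``
    (base-call noise). Returns the consensus and the generating pair.
    """
    rng = _rng(seed)
    g_like, t_like = _alleles_by_site_base(db, site_label)
    pools = {GG: (g_like, g_like), GT: (g_like, t_like), TT: (t_like, t_like)}
    if genotype not in pools:
        raise InputError(f"cannot build a consensus for genotype {genotype!r}")
    pool_a, pool_b = pools[genotype]
    if not pool_a or not pool_b:
        raise InputError(
            f"database lacks an allele class required for genotype {genotype} "
            f"at {site_label}"
        )
    pair = (pool_a[rng.integers(len(pool_a))], pool_b[rng.integers(len(pool_b))])
    seq = list(expected_consensus(db, *pair).seq)
    if error_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
        for i in hits:
            choices = [c for c in _IUPAC_LIST if c != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
    return ConsensusSeq(sample_id=sample_id, seq="".join(seq)), pair


def simulate_endpoint(
    genotype: str,
    centroids: dict[str, tuple[float, float]] = DEFAULT_CENTROIDS,
    noise_sd: float = DEFAULT_ENDPOINT_NOISE_SD,
    dropout_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    well_id: str = "A1",
    sample_id: str = "sim",
) -> EndpointSignal:
    """Bivariate Gaussian endpoint signal around the genotype's centroid.

    With probability ``dropout_rate`` the well fails to amplify and emits a
    near-zero signal in both channels (an "unknown" well).
    """
    rng = _rng(seed)
    if genotype not in centroids:
        raise InputError(f"no centroid for genotype {genotype!r}")
    if rng.random() < dropout_rate:
        fx, fy = rng.uniform(0.0, 0.5, size=2)
    else:
        cx, cy = centroids[genotype]
        fx, fy = rng.normal((cx, cy), noise_sd)
    return EndpointSignal(
        well_id=well_id, sample_id=sample_id, fx=max(float(fx), 0.0), fy=max(float(fy), 0.0)
    )


def melt_fraction(
    temps: np.ndarray, components: tuple[tuple[float, float], ...],
    width: float = DEFAULT_TRANSITION_WIDTH,
) -> np.ndarray:
    """Fraction of intact duplex vs temperature for a mixture of transitions."""
    temps = np.asarray(temps, dtype=float)
    out = np.zeros_like(temps)
    for weight, tm in components:
        out += weight / (1.0 + np.exp((temps - tm) / width))
    return out


def simulate_melt(
    genotype: str,
    grid: np.ndarray = DEFAULT_MELT_GRID,
    tm_components: dict[str, tuple[tuple[float, float], ...]] = DEFAULT_TM_COMPONENTS,
    noise_sd: float = DEFAULT_MELT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
    well_id: str = "A1",
    sample_id: str = "sim",
    amplitude: float = 40.0,
    baseline: float = 2.0,
) -> MeltCurve:
    """Raw (un-normalized) melt curve for one well of a given genotype."""
    rng = _rng(seed)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 60.0 or grid[-1] > 95.0:
        raise InputError("melt grid must lie within the 60-95 degC acquisition ramp")
    if genotype not in tm_components:
        raise InputError(f"no melt model for genotype {genotype!r}")
    signal = baseline + amplitude * melt_fraction(grid, tm_components[genotype])
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=grid.shape)
    return MeltCurve(well_id=well_id, sample_id=sample_id, temps=grid, fluor=signal)


def hrm_references(
    grid: np.ndarray = DEFAULT_MELT_GRID,
    tm_components: dict[str, tuple[tuple[float, float], ...]] = DEFAULT_TM_COMPONENTS,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> list:
    """Noise-free normalized reference melt curves, one per genotype."""
    from .signals import HRMReference, normalize_melt

    refs = []
    for g in GENOTYPES:
        raw = simulate_melt(g, grid=grid, tm_components=tm_components, noise_sd=0.0,
                            well_id=f"ref_{g}", sample_id=f"ref_{g}")
        norm = normalize_melt(raw, pre_window, post_window)
        refs.append(HRMReference(genotype=g, temps=norm.temps, values=norm.fluor))
    return refs


def simulate_study_samples(
    spec: CohortSpec,
    db: AlleleDB | None = None,
    site_label: str = "NT-26",
    error_rate: float = 0.0,
    noise_sd: float = DEFAULT_ENDPOINT_NOISE_SD,
    dropout_rate: float = 0.0,
    melt_noise_sd: float = DEFAULT_MELT_NOISE_SD,
    n_melt_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
) -> list[SimulatedSample]:
    """Simulate one cohort end to end: genotypes plus all three readouts."""
    rng = _rng(seed)
    db = db or toy_db()
    genotypes = simulate_cohort(spec, rng)
    samples = []
    for i, g in enumerate(genotypes):
        sid = f"{spec.label}_{i:04d}"
        consensus, pair = genotype_to_consensus(
            g, db, site_label=site_label, error_rate=error_rate, seed=rng, sample_id=sid
        )
        endpoint = simulate_endpoint(
            g, noise_sd=noise_sd, dropout_rate=dropout_rate, seed=rng,
            well_id=f"EP_{i:04d}", sample_id=sid,
        )
        melts = [
            simulate_melt(
                g, noise_sd=melt_noise_sd, seed=rng,
                well_id=f"HRM_{i:04d}_{r}", sample_id=sid,
            )
            for r in range(n_melt_replicates)
        ]
        samples.append(
            SimulatedSample(
                sample_id=sid, genotype=g, allele_pair=pair,
                consensus=consensus, endpoint=endpoint, melt_wells=melts,
            )
        )
    return samples
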