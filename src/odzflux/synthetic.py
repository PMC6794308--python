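"""Synthetic study-condition generator with known ground truth.

Every input the analysis chain consumes can be generated here: a wind
history, a mixed-layer dissolved-gas sample consistent with known true GPP
and NCP, a trap-flux profile with a known in-situ production injection, a
placement table drawn from a known community, and peptide tables with exact
overlap structure.  Each generator is the forward model of the corresponding
inverse computation, so noise-free round trips are exact and noisy ones are
statistically calibrated.

Defaults describe an oligotrophic offshore ODZ station: mixed layer ~25 m
at 27 °C / 34.5 PSU, trade winds averaging 7 m s⁻¹, GPP ~60 and NCP
~3 mmol O₂ m⁻² d⁻¹, traps at 105/150/750 m with a 0.39 mmol C m⁻² d⁻¹
background flux and 0.27 mmol C m⁻² d⁻¹ of production injected inside the
ODZ, and a free-living cyanophage:host ratio of 35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .gas_exchange import HydroState, WindRecord
from .placement import GeneMeta, MetagenomeSample, PeptideObservation, PlacementRead
from .productivity import IsotopeConstants, TripleOxygenSample
from .stoich import TrapFlux

__all__ = [
    "ScenarioConfig",
    "make_wind_series",
    "make_toi_sample",
    "make_trap_profile",
    "make_placement_table",
    "make_peptide_tables",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth and noise levels for one synthetic station."""

    seed: int = 0
    n_days: int = 60
    mean_wind: float = 7.0  # m s⁻¹
    wind_noise: float = 0.25  # lognormal sigma (0 → constant wind)
    true_gpp: float = 60.0  # mmol O₂ m⁻² d⁻¹
    true_ncp: float = 3.0  # mmol O₂ m⁻² d⁻¹
    mld: float = 25.0  # m
    temperature: float = 27.0  # °C
    salinity: float = 34.5  # PSU
    trap_depths: tuple[float, ...] = (105.0, 150.0, 750.0)
    background_flux: float = 0.39  # mmol C m⁻² d⁻¹ at the shallowest trap
    attenuation_exp: float = 0.41  # Martin-curve exponent below the injection
    in_situ_production: float = 0.27  # mmol C m⁻² d⁻¹ injected between two depths
    injection_depths: tuple[float, float] = (105.0, 150.0)
    cn_ratio: float = 106.0 / 16.0  # molar C:N of sinking matter
    community: Mapping[str, float] = field(
        default_factory=lambda: {
            "Prochlorococcus_LLIV_V": 0.55,
            "Prochlorococcus_LLI": 0.25,
            "Synechococcus": 0.15,
            "NC1": 0.05,
        }
    )
    virus_host_ratio: float = 35.0
    library_size: int = 100_000
    marker_reads: int = 20_000  # reads on the genotyping marker per library
    contaminant_fraction: float = 0.012  # fraction given branch length > 2
    sigma_delta17: float = 0.002  # per mil (≈2 per meg on ¹⁷Δ)
    sigma_delta18: float = 0.004  # per mil
    sigma_o2ar: float = 0.001  # on the supersaturation
    flux_noise: float = 0.0  # lognormal sigma on trap fluxes

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be ≥ 1")
        if self.true_gpp < 0 or self.mean_wind < 0:
            raise ValueError("true GPP and mean wind must be ≥ 0")
        if self.library_size <= 0 or self.marker_reads <= 0:
            raise ValueError("library sizes must be > 0")
        total = sum(self.community.values())
        if self.community and abs(total - 1.0) > 1e-9:
            raise ValueError(f"community abundances sum to {total}, not 1")
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant fraction must be in [0, 1)")

    @property
    def hydro(self) -> HydroState:
        return HydroState(self.temperature, self.salinity, self.mld)


def make_wind_series(cfg: ScenarioConfig) -> list[WindRecord]:
    """Daily 10 m wind speeds: lognormal around the configured mean.

    Lognormal daily speeds are positive and right-skewed like trade-wind
    records; ``wind_noise`` is the log-scale sigma, and the distribution is
    mean-corrected so the expected speed equals ``mean_wind``.  A zero mean
    with zero noise gives a flat-calm series.
    """
    if cfg.n_days < 1:
        raise ValueError("n_days must be ≥ 1")
    rng = np.random.default_rng(cfg.seed)
    if cfg.mean_wind == 0.0:
        speeds = np.zeros(cfg.n_days)
    elif cfg.wind_noise == 0.0:
        speeds = np.full(cfg.n_days, cfg.mean_wind)
    else:
        mu = math.log(cfg.mean_wind) - cfg.wind_noise**2 / 2.0
        speeds = rng.lognormal(mu, cfg.wind_noise, cfg.n_days)
    return [
        WindRecord(date=f"day{-(cfg.n_days - 1) + i:+d}", u10=float(u))
        for i, u in enumerate(speeds)
    ]


def make_toi_sample(
    cfg: ScenarioConfig,
    k: float,
    o2eq: float,
    consts: IsotopeConstants | None = None,
    station: str = "SYN",
) -> TripleOxygenSample:
    """Forward-model a dissolved-gas sample from true GPP and NCP.

    Inverts the steady-state TOI balance: the dissolved ¹⁷Δ is placed where
    ``gpp_from_toi`` returns exactly ``true_gpp`` for the given k and
    [O₂]eq, then (δ¹⁷O, δ¹⁸O) are chosen on the equilibrium δ¹⁸O with that
    excess.  Δ(O₂/Ar) is set to true_ncp/(k·[O₂]eq).  Configured noise is
    added after the exact inversion.
    """
    if k <= 0:
        raise ValueError("piston velocity must be > 0")
    consts = consts or IsotopeConstants()
    flux = k * o2eq
    # solve GPP = F·(Δ−Δeq)/(Δphoto−Δ) for Δ
    d17 = (cfg.true_gpp * consts.d17_photo + flux * consts.d17_eq) / (
        cfg.true_gpp + flux
    )
    delta18 = consts.delta18_eq
    # δ17 from the excess definition: ln(1+δ17/1000) = Δ·1e-6 + λ·ln(1+δ18/1000)
    delta17 = (
        math.expm1(d17 * 1e-6 + consts.lambda_ * math.log1p(delta18 / 1000.0)) * 1000.0
    )
    o2ar = cfg.true_ncp / flux
    rng = np.random.default_rng(cfg.seed + 1)
    noise = rng.standard_normal(3)
    return TripleOxygenSample(
        station=station,
        date="day+0",
        delta17=delta17 + noise[0] * cfg.sigma_delta17,
        delta18=delta18 + noise[1] * cfg.sigma_delta18,
        o2ar_supersat=o2ar + noise[2] * cfg.sigma_o2ar,
        sigma_delta17=cfg.sigma_delta17,
        sigma_delta18=cfg.sigma_delta18,
        sigma_o2ar=cfg.sigma_o2ar,
    )


def make_trap_profile(cfg: ScenarioConfig) -> tuple[list[TrapFlux], dict]:
    """Trap fluxes: background plus an in-situ production pulse.

    The sinking-flux increase observed between two trap depths inside the
    ODZ is modeled additively: the background flux holds at its shallow
    value down to the lower injection depth (in-situ production offsets the
    attenuation there), the injected flux appears at that depth, and the
    combined flux attenuates below it with a Martin-type power law.  With
    the defaults this area-matches the 0.39 / 0.66 / 0.34 mmol C m⁻² d⁻¹
    profile at 105 / 150 / 750 m.  Returns the profile and a ground-truth
    dict (true contribution fraction at the injection depth).
    """
    depths = cfg.trap_depths
    if len(depths) < 2:
        raise ValueError("need at least 2 trap depths")
    if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
        raise ValueError("trap depths must be strictly increasing")
    z_inj = cfg.injection_depths[1]
    rng = np.random.default_rng(cfg.seed + 2)
    top_total = cfg.background_flux + cfg.in_situ_production
    traps: list[TrapFlux] = []
    for z in depths:
        if z < z_inj:
            flux = cfg.background_flux
        else:
            flux = top_total * (z / z_inj) ** -cfg.attenuation_exp
        if cfg.flux_noise > 0:
            flux *= rng.lognormal(-cfg.flux_noise**2 / 2.0, cfg.flux_noise)
        n_flux = flux / cfg.cn_ratio * 1000.0  # µmol N m⁻² d⁻¹
        traps.append(TrapFlux(depth=z, c_flux=flux, n_flux=n_flux))
    truth = {
        "in_situ_production": cfg.in_situ_production,
        "contribution_fraction": (
            cfg.in_situ_production / top_total if cfg.in_situ_production > 0 else 0.0
        ),
    }
    return traps, truth


# marker genes of the synthetic community
_HOST_MARKER = GeneMeta(gene="rpoB", ref_length=1100.0, length_unit="aa")
_VIRUS_MARKER = GeneMeta(gene="viral_DNApol", ref_length=700.0, length_unit="aa")


def make_placement_table(
    cfg: ScenarioConfig,
    gene: str = "ITS",
    gene_length: float = 550.0,
    copy_number: Mapping[str, float] | None = None,
) -> tuple[list[PlacementRead], list[MetagenomeSample], list[GeneMeta], dict]:
    """Draw a placement table from the configured community.

    Marker reads are multinomial over clades with probabilities ∝
    abundance × copy number (equal gene length within one marker); a
    ``contaminant_fraction`` of reads gets a pendant branch length of 3.0
    so the quality filter has something to remove.  Virus- and host-marker
    reads are drawn so the length-normalized virus/host ratio matches
    ``virus_host_ratio`` in expectation.

    Returns (reads, samples, gene metadata, ground truth).
    """
    if not cfg.community:
        raise ValueError("community must be non-empty")
    total = sum(cfg.community.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"community abundances sum to {total}, not 1")
    copy_number = dict(copy_number or {})
    rng = np.random.default_rng(cfg.seed + 3)

    clades = sorted(cfg.community)
    weights = np.array(
        [cfg.community[c] * copy_number.get(c, 1.0) for c in clades], dtype=float
    )
    probs = weights / weights.sum()
    counts = rng.multinomial(cfg.marker_reads, probs)

    n_contam = int(round(cfg.contaminant_fraction * cfg.marker_reads))
    contam_ids = set(rng.choice(cfg.marker_reads, size=n_contam, replace=False))

    sample = MetagenomeSample(
        sample_id="synthetic_0", library_size=cfg.library_size, depth=120.0
    )
    reads: list[PlacementRead] = []
    i = 0
    for clade, n in zip(clades, counts):
        for _ in range(n):
            contaminated = i in contam_ids
            reads.append(
                PlacementRead(
                    read_id=f"r{i:07d}",
                    gene=gene,
                    clade=clade,
                    branch_length=3.0 if contaminated else float(rng.uniform(0.0, 1.5)),
                    read_len=150,
                    sample_id=sample.sample_id,
                )
            )
            i += 1

    # virus & host markers: host count fixed, virus count set so that the
    # length-normalized ratio equals the target in expectation
    n_host = 2000
    n_virus_mean = (
        cfg.virus_host_ratio
        * n_host
        * _VIRUS_MARKER.ref_length
        / _HOST_MARKER.ref_length
    )
    n_virus = int(rng.poisson(n_virus_mean))
    for j in range(n_host):
        reads.append(
            PlacementRead(
                read_id=f"h{j:07d}",
                gene=_HOST_MARKER.gene,
                clade="Cyanobacteria",
                branch_length=float(rng.uniform(0.0, 1.5)),
                read_len=150,
                sample_id=sample.sample_id,
            )
        )
    for j in range(n_virus):
        reads.append(
            PlacementRead(
                read_id=f"v{j:07d}",
                gene=_VIRUS_MARKER.gene,
                clade="Cyanomyovirus_II",
                branch_length=float(rng.uniform(0.0, 1.5)),
                read_len=150,
                sample_id=sample.sample_id,
            )
        )

    genes = [
        GeneMeta(gene=gene, ref_length=gene_length, length_unit="nt", copy_number=copy_number),
        _HOST_MARKER,
        _VIRUS_MARKER,
    ]
    truth = {
        "community": dict(cfg.community),
        "marker_reads": cfg.marker_reads,
        "contaminant_fraction": n_contam / cfg.marker_reads,
        "virus_host_ratio": cfg.virus_host_ratio,
    }
    return reads, [sample], genes, truth


def make_peptide_tables(
    cfg: ScenarioConfig,
    sizes: Mapping[str, int],
    overlaps: Mapping[tuple[str, str], float],
    taxon: str = "Cyanobacteria",
) -> list[PeptideObservation]:
    """Construct peptide sets realizing pairwise overlaps exactly.

    ``overlaps[(a, b)]`` is the fraction of sample *a*'s peptides shared
    with sample *b*; the shared block is |a|·fraction peptides drawn from a
    common pool, the rest are private.  Overlap specifications implying an
    intersection larger than either set are rejected.  Only pairwise
    structure is controlled; unlisted pairs are disjoint.
    """
    for (a, b), frac in overlaps.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"overlap for {(a, b)} outside [0, 1]: {frac}")
        if a not in sizes or b not in sizes:
            raise ValueError(f"overlap names unknown sample in {(a, b)}")
        if round(frac * sizes[a]) > sizes[b]:
            raise ValueError(
                f"requested intersection {round(frac * sizes[a])} exceeds |{b}| = {sizes[b]}"
            )
    obs: list[PeptideObservation] = []
    assigned: dict[str, list[str]] = {s: [] for s in sizes}
    pool = 0
    for (a, b), frac in overlaps.items():
        n_shared = round(frac * sizes[a])
        shared = [f"PEP{pool + i:06d}" for i in range(n_shared)]
        pool += n_shared
        assigned[a].extend(shared)
        assigned[b].extend(shared)
    for s, n in sizes.items():
        have = len(assigned[s])
        if have > n:
            raise ValueError(f"overlap structure over-fills sample {s!r} ({have} > {n})")
        private = [f"PEP{pool + i:06d}" for i in range(n - have)]
        pool += n - have
        assigned[s].extend(private)
    for s, peps in assigned.items():
        for p in peps:
            obs.append(PeptideObservation(sample_id=s, peptide=p, taxon=taxon))
    return obs
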