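"""Seeded generators for behavioral traces and protein-intensity tables.

Both generators emit data shaped like the study's two readouts together
with a machine-readable ground-truth record of every injected effect,
so each pipeline stage has a closed-loop test surface without any
external download.

Behavioral traces emulate the stereotyped larval phenotypes: a dark
baseline, reduced activity under light, a surge at the light-to-dark
transition decaying back to baseline, startle spikes locked to the
stimulus seconds, and a geometric within-bout habituation decline.
Group-level effects are a multiplicative dark-surge hyperactivity
factor and a habituation-acceleration factor (an exponent multiplier on
the per-stimulus decay).  Per-bin noise is Gaussian truncated at zero
(activity is non-negative); wells additionally carry a lognormal
activity multiplier for individual larva variability.

Protein tables emulate species x protein-group intensities across
stabilization/exposure/recovery phases in several bioreactors, with
injectable per-species and per-pathway multiplicative phase effects,
bioreactor-level random effects, and lognormal measurement noise, plus
a synthetic KO/pathway annotation map with controllable coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import ActivityTrace, AssayProtocol, Schedule, build_schedule
from .sihumix import PHASES, SIHUMIX_SPECIES, PathwayMap

# ---------------------------------------------------------------------------
# behavioral traces
# ---------------------------------------------------------------------------

#: the study's six groups: 2 colonization statuses x 3 exposures
DEFAULT_GROUPS: tuple[str, ...] = (
    "SIHUMIx:DMSO",
    "SIHUMIx:AZX0.6",
    "SIHUMIx:AZX1.68",
    "depleted:DMSO",
    "depleted:AZX0.6",
    "depleted:AZX1.68",
)


@dataclass(frozen=True)
class GroupEffect:
    """Group-level deviations from the control phenotype."""

    hyperactivity: float = 1.0            # multiplier on the dark-surge amplitude
    habituation_acceleration: float = 1.0  # exponent multiplier on the bout decay

    def __post_init__(self) -> None:
        if self.hyperactivity <= 0 or self.habituation_acceleration <= 0:
            raise ValueError("group effect multipliers must be > 0")


@dataclass(frozen=True)
class BehaviorSimSpec:
    """Generator settings; defaults emulate the study's plate design.

    Activity is in arbitrary pixel-intensity-change units per second.
    """

    protocol: AssayProtocol = field(default_factory=AssayProtocol)
    n_wells: int = 45
    groups: tuple[str, ...] = DEFAULT_GROUPS
    effects: dict = field(default_factory=dict)  # group label -> GroupEffect
    baseline_dark: float = 10.0
    baseline_light: float = 5.0
    vmr_surge_amplitude: float = 40.0
    vmr_surge_tau: float = 150.0          # s, dark-surge exponential decay
    vsr_amplitude: float = 60.0
    asr_low_amplitude: float = 30.0       # 65 dB stimuli (ASR1)
    asr_high_amplitude: float = 60.0      # 75 dB stimuli (ASR2/3, bouts)
    bout_response_amplitude: float = 60.0
    bout_decay: float = 0.93              # geometric per-stimulus habituation
    noise_scale: float = 5.0              # truncated-Gaussian sd per 1-s bin
    well_effect_scale: float = 0.3        # lognormal sigma of per-well multiplier
    flasks_per_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.noise_scale < 0 or self.well_effect_scale < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 < self.bout_decay <= 1:
            raise ValueError("bout_decay must be in (0, 1]")
        for g, eff in self.effects.items():
            if g not in self.groups:
                raise ValueError(f"effect refers to unknown group {g!r}")
            if not isinstance(eff, GroupEffect):
                raise ValueError("effects values must be GroupEffect instances")

    def effect(self, group: str) -> GroupEffect:
        return self.effects.get(group, GroupEffect())


@dataclass
class BehaviorGroundTruth:
    """Injected means, recorded independently of the generated data."""

    spec: BehaviorSimSpec
    mean_traces: dict[str, np.ndarray]          # group -> noiseless mean trace
    expected_endpoints: pd.DataFrame            # group x endpoint expected values


def expected_mean_trace(spec: BehaviorSimSpec, group: str, schedule: Schedule | None = None) -> np.ndarray:
    """Noiseless per-second mean activity for one group (well multiplier 1)."""
    sched = schedule if schedule is not None else build_schedule(spec.protocol)
    p = spec.protocol
    eff = spec.effect(group)
    mean = np.full(sched.total_length, spec.baseline_dark)

    light_start = p.acclimation_duration
    dark_start = light_start + p.light_phase_duration
    mean[light_start:dark_start] = spec.baseline_light
    # dark-phase surge decaying back to baseline over the whole dark block
    tail = np.arange(dark_start + p.startle_window, dark_start + p.post_light_dark_duration)
    mean[tail] += (
        eff.hyperactivity
        * spec.vmr_surge_amplitude
        * np.exp(-(tail - tail[0]) / spec.vmr_surge_tau)
    )
    # visual startles ride on the phase they open
    for name in ("VSR1", "VSR2"):
        mean[sched.interval_seconds[name]] += spec.vsr_amplitude
    # acoustic startles
    mean[sched.stimulus_onsets["ASR1"]] += spec.asr_low_amplitude
    mean[sched.stimulus_onsets["ASR2"]] += spec.asr_high_amplitude
    mean[sched.stimulus_onsets["ASR3"]] += spec.asr_high_amplitude
    # habituation bouts: geometric within-bout decline, accelerated by the group effect
    i = np.arange(p.stimuli_per_bout)
    responses = spec.bout_response_amplitude * spec.bout_decay ** (
        eff.habituation_acceleration * i
    )
    for onsets in sched.bout_stimulus_onsets:
        mean[onsets] += responses
    return mean


def simulate_activity_matrix(
    spec: BehaviorSimSpec, schedule: Schedule | None = None
) -> tuple[np.ndarray, pd.DataFrame, BehaviorGroundTruth]:
    """Simulate all wells as one (n_wells_total, n_seconds) matrix.

    Returns ``(activity, metadata, ground_truth)``.  Metadata carries
    well_id, group, colonization, treatment, concentration and a flask
    assignment cycling over ``flasks_per_group`` flasks per group.
    """
    from .endpoints import ENDPOINT_NAMES, build_endpoint_table  # local: avoid cycle

    sched = schedule if schedule is not None else build_schedule(spec.protocol)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), 0xBE]))
    means = {g: expected_mean_trace(spec, g, sched) for g in spec.groups}

    blocks, meta_rows = [], []
    for gi, g in enumerate(spec.groups):
        mult = (
            rng.lognormal(mean=0.0, sigma=spec.well_effect_scale, size=spec.n_wells)
            if spec.well_effect_scale > 0
            else np.ones(spec.n_wells)
        )
        base = mult[:, None] * means[g][None, :]
        if spec.noise_scale > 0:
            base = base + rng.normal(0.0, spec.noise_scale, size=base.shape)
        blocks.append(np.clip(base, 0.0, None))
        colonization, treatment = g.split(":", 1) if ":" in g else (g, g)
        concentration = 0.0
        if treatment.startswith("AZX"):
            concentration = float(treatment[3:])
        for w in range(spec.n_wells):
            meta_rows.append(
                {
                    "well_id": f"{g}|W{w + 1:03d}",
                    "group": g,
                    "colonization": colonization,
                    "treatment": treatment,
                    "concentration": concentration,
                    "flask": f"{g}|F{w % spec.flasks_per_group + 1:02d}",
                }
            )
    activity = np.concatenate(blocks, axis=0)
    metadata = pd.DataFrame(meta_rows)

    # expected endpoint values: segment the noiseless mean traces
    mean_traces = [
        ActivityTrace(well_id=g, values=means[g]) for g in spec.groups
    ]
    expected = build_endpoint_table(mean_traces, sched)
    gt = BehaviorGroundTruth(
        spec=spec,
        mean_traces=means,
        expected_endpoints=expected[list(ENDPOINT_NAMES)],
    )
    return activity, metadata, gt


def simulate_traces(
    spec: BehaviorSimSpec, schedule: Schedule | None = None
) -> tuple[list[ActivityTrace], pd.DataFrame, BehaviorGroundTruth]:
    """Simulate per-well :class:`ActivityTrace` objects (plus metadata
    and ground truth); seeded and bit-reproducible."""
    activity, metadata, gt = simulate_activity_matrix(spec, schedule)
    traces = [
        ActivityTrace(
            well_id=row.well_id,
            values=activity[i],
            colonization=row.colonization,
            treatment=row.treatment,
            concentration=row.concentration,
            flask=row.flask,
        )
        for i, row in enumerate(metadata.itertuples())
    ]
    return traces, metadata, gt


def hyperactivity_for_shift(
    spec: BehaviorSimSpec, group: str, shift: float, schedule: Schedule | None = None
) -> float:
    """Hyperactivity multiplier whose expected VMR2 mean shift is ``shift``.

    The VMR2 endpoint mean is linear in the multiplier h:
    ``E[VMR2] = exp(sigma_w^2 / 2) * (baseline_part + h * surge_part)``
    (the lognormal well multiplier scales the whole mean), so
    ``h = 1 + shift / (exp(sigma_w^2 / 2) * surge_part)``.  Truncation of
    the additive bin noise at zero is negligible for VMR2 at the default
    signal-to-noise ratio and is ignored here.
    """
    from dataclasses import replace

    from .endpoints import build_endpoint_table

    sched = schedule if schedule is not None else build_schedule(spec.protocol)
    traces = []
    for h in (1.0, 2.0):
        probe = replace(spec, effects={**spec.effects, group: GroupEffect(hyperactivity=h)})
        traces.append(ActivityTrace(f"h{h}", expected_mean_trace(probe, group, sched)))
    table = build_endpoint_table(traces, sched)
    surge_part = table["VMR2"].iloc[1] - table["VMR2"].iloc[0]
    if surge_part <= 0:
        raise ValueError("spec has no dark-phase surge to scale")
    return 1.0 + shift / (np.exp(spec.well_effect_scale**2 / 2) * surge_part)


# ---------------------------------------------------------------------------
# protein-intensity tables
# ---------------------------------------------------------------------------

#: plausible steady-state proteome-weighted shares of the consortium
DEFAULT_BASELINE_SHARES: dict[str, float] = {
    "Anaerostipes caccae": 0.08,
    "Bacteroides thetaiotaomicron": 0.28,
    "Bifidobacterium longum": 0.07,
    "Blautia producta": 0.12,
    "Clostridium butyricum": 0.10,
    "Thomasclavelia ramosa": 0.05,
    "Escherichia coli": 0.20,
    "Lactiplantibacillus plantarum": 0.10,
}


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Generator settings for synthetic species x protein tables.

    Defaults follow the cultivation design: 4 bioreactors sampled daily
    over a 3-day stabilization, 7-day exposure and 4-day recovery.
    """

    n_bioreactors: int = 4
    days_per_phase: tuple = (("stabilization", 3), ("exposure", 7), ("recovery", 4))
    baseline_shares: tuple = tuple(DEFAULT_BASELINE_SHARES.items())
    phase_species_effects: tuple = ()   # ((phase, species, multiplier), ...)
    proteins_per_species: int = 40
    n_pathways: int = 12
    kos_per_pathway: int = 8            # detected KOs assigned per pathway
    pathway_coverage: float = 0.5       # detected / total KOs of each pathway
    pathway_phase_folds: tuple = ()     # ((pathway_id, phase, fold), ...)
    bioreactor_effect_scale: float = 0.1  # lognormal sigma per (bioreactor, species)
    noise_scale: float = 0.25           # lognormal sigma per measurement
    total_intensity: float = 1e9
    seed: int = 0

    def __post_init__(self) -> None:
        shares = dict(self.baseline_shares)
        total = sum(shares.values())
        if any(v <= 0 for v in shares.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline shares must be positive and sum to 1 (got {total})")
        if self.n_bioreactors < 1 or self.proteins_per_species < 1:
            raise ValueError("n_bioreactors and proteins_per_species must be >= 1")
        if not 0 < self.pathway_coverage <= 1:
            raise ValueError("pathway_coverage must be in (0, 1]")
        for phase, _species, mult in self.phase_species_effects:
            if phase not in PHASES or mult <= 0:
                raise ValueError(f"bad species effect ({phase}, {mult})")
        for _pw, phase, fold in self.pathway_phase_folds:
            if phase not in PHASES or fold <= 0:
                raise ValueError(f"bad pathway fold ({phase}, {fold})")
        if self.n_pathways * self.kos_per_pathway > len(shares) * self.proteins_per_species:
            raise ValueError("more pathway KO slots than protein groups available")


@dataclass
class ProteomeGroundTruth:
    spec: ProteomeSimSpec
    expected_shares: pd.DataFrame   # phase x species expected community shares
    pathway_folds: dict             # (pathway, phase) -> injected fold
    species_effects: dict           # (phase, species) -> multiplier


def _expected_shares(spec: ProteomeSimSpec) -> pd.DataFrame:
    shares = dict(spec.baseline_shares)
    effects = {(p, s): m for p, s, m in spec.phase_species_effects}
    rows = {}
    for phase in PHASES:
        raw = {s: shares[s] * effects.get((phase, s), 1.0) for s in shares}
        total = sum(raw.values())
        rows[phase] = {s: v / total for s, v in raw.items()}
    return pd.DataFrame(rows).T  # phases x species


def simulate_proteome(
    spec: ProteomeSimSpec,
) -> tuple[pd.DataFrame, PathwayMap, ProteomeGroundTruth]:
    """Generate the long-format protein table, its KO/pathway map and
    the ground truth of injected effects.

    Intensity model per (sample, protein group):
    ``total x species_share x protein_weight x phase_species_effect x
    pathway_phase_fold x bioreactor_species_effect x lognormal noise``.
    With all noise scales at zero and no injected effects the community
    profile round-trips the baseline share vector exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), 0xF7]))
    shares = dict(spec.baseline_shares)
    species = list(shares)

    # protein universe with within-species weights summing to 1
    proteins = []
    for s in species:
        short = "".join(w[0] for w in s.split()).upper()
        weights = rng.dirichlet(np.full(spec.proteins_per_species, 2.0))
        for j in range(spec.proteins_per_species):
            proteins.append(
                {
                    "protein_group": f"{short}_PG{j + 1:04d}",
                    "species": s,
                    "weight": weights[j],
                    "ko": f"K{len(proteins) + 1:05d}",
                }
            )
    prot = pd.DataFrame(proteins)

    # synthetic pathway map: round-robin KO assignment so pathways span
    # species; undetected padding KOs set the coverage fraction
    pathway_to_kos: dict[str, set] = {}
    ko_pathway: dict[str, str] = {}
    kos = prot["ko"].tolist()
    cursor = 0
    pad_counter = 0
    for pw in range(spec.n_pathways):
        pw_id = f"pw{pw + 1:03d}"
        detected = kos[cursor:cursor + spec.kos_per_pathway]
        cursor += spec.kos_per_pathway
        n_total = round(spec.kos_per_pathway / spec.pathway_coverage)
        padding = [f"Kx{pad_counter + k:05d}" for k in range(n_total - len(detected))]
        pad_counter += len(padding)
        pathway_to_kos[pw_id] = set(detected) | set(padding)
        for ko in detected:
            ko_pathway[ko] = pw_id
    prot["pathway"] = prot["ko"].map(ko_pathway).fillna("")

    effects = {(p, s): m for p, s, m in spec.phase_species_effects}
    folds = {(pw, p): f for pw, p, f in spec.pathway_phase_folds}

    rows = []
    for r in range(1, spec.n_bioreactors + 1):
        reactor = f"BR{r}"
        reactor_mult = {
            s: (rng.lognormal(0.0, spec.bioreactor_effect_scale) if spec.bioreactor_effect_scale > 0 else 1.0)
            for s in species
        }
        day = 0
        for phase, n_days in spec.days_per_phase:
            for _d in range(n_days):
                day += 1
                sample_id = f"{reactor}_d{day:02d}_{phase}"
                base = (
                    spec.total_intensity
                    * prot["species"].map(shares).to_numpy()
                    * prot["weight"].to_numpy()
                    * prot["species"].map(lambda s: effects.get((phase, s), 1.0)).to_numpy()
                    * prot["pathway"].map(lambda pw: folds.get((pw, phase), 1.0)).to_numpy()
                    * prot["species"].map(reactor_mult).to_numpy()
                )
                if spec.noise_scale > 0:
                    base = base * rng.lognormal(0.0, spec.noise_scale, size=base.size)
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "bioreactor": reactor,
                            "phase": phase,
                            "species": prot["species"],
                            "protein_group": prot["protein_group"],
                            "intensity": base,
                            "ko": prot["ko"],
                            "pathways": prot["pathway"],
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)

    ko_to_pg = {
        ko: frozenset(sub["protein_group"]) for ko, sub in prot.groupby("ko", observed=True)
    }
    pmap = PathwayMap(
        pathway_to_kos={k: frozenset(v) for k, v in pathway_to_kos.items()},
        ko_to_protein_groups=ko_to_pg,
    )
    gt = ProteomeGroundTruth(
        spec=spec,
        expected_shares=_expected_shares(spec),
        pathway_folds=folds,
        species_effects=effects,
    )
    return table, pmap, gt
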