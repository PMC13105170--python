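"""Metaproteome-weighted community and pathway statistics for SIHUMIx.

SIHUMIx is a defined eight-species simplified human intestinal
microbiota cultured in continuous bioreactors through stabilization,
chemical-exposure and recovery phases.  This module implements the
statistics applied to its metaproteomic readout:

* proteome-weighted community structure: per-sample species shares of
  total species-assigned protein intensity;
* phase comparisons of per-bioreactor mean shares via tie-corrected
  Kruskal-Wallis tests with Dunn's post-hoc z tests and
  Benjamini-Hochberg correction;
* KEGG-ortholog pathway intensity aggregation with functional-coverage
  (>= 15% of the pathway's KOs detected) and protein-count (>= 5)
  retention filters, and stabilization-vs-exposure selection by
  |Log2FC| >= 0.2 of mean relative pathway intensity combined with a
  Kruskal-Wallis p < 0.05;
* Bray-Curtis dissimilarities, one-way PERMANOVA with permutation
  p-values (pairwise variant Hochberg-adjusted), and centered PCA
  ordination;
* the exposure-design dose arithmetic anchoring the bioreactor
  concentration to a fraction of the acceptable daily intake (ADI).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .bootstats import adjust_pvalues, substream

#: the eight consortium members
SIHUMIX_SPECIES: tuple[str, ...] = (
    "Anaerostipes caccae",
    "Bacteroides thetaiotaomicron",
    "Bifidobacterium longum",
    "Blautia producta",
    "Clostridium butyricum",
    "Thomasclavelia ramosa",
    "Escherichia coli",
    "Lactiplantibacillus plantarum",
)

PHASES: tuple[str, ...] = ("stabilization", "exposure", "recovery")

REQUIRED_COLUMNS = ("sample_id", "bioreactor", "phase", "species", "protein_group", "intensity")


def validate_protein_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format protein-intensity table contract."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"protein table lacks required columns: {missing}")
    bad = table.index[table["intensity"] < 0]
    if len(bad):
        raise ValueError(f"negative intensity in rows {list(bad[:5])}")
    unknown_phases = set(table["phase"]) - set(PHASES)
    if unknown_phases:
        raise ValueError(f"unknown cultivation phases: {sorted(unknown_phases)}")
    return table


# ---------------------------------------------------------------------------
# community structure
# ---------------------------------------------------------------------------

def community_profile(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample species shares of species-assigned protein intensity.

    Returns ``(shares, unassigned_fraction)``: ``shares`` is a
    samples x species frame whose rows sum to 1; rows labelled
    "unassigned" are excluded from the denominator and their per-sample
    mass fraction is reported separately.
    """
    validate_protein_table(table)
    totals = table.groupby(["sample_id", "species"], observed=True)["intensity"].sum().unstack(fill_value=0.0)
    unassigned = totals.pop("unassigned") if "unassigned" in totals.columns else pd.Series(0.0, index=totals.index)
    assigned_total = totals.sum(axis=1)
    zero = assigned_total.index[assigned_total <= 0]
    if len(zero):
        raise ValueError(f"samples with zero species-assigned intensity: {list(zero)}")
    shares = totals.div(assigned_total, axis=0)
    unassigned_fraction = unassigned / (assigned_total + unassigned)
    return shares, unassigned_fraction


def bioreactor_phase_means(
    profiles: pd.DataFrame, meta: pd.DataFrame, value_cols=None
) -> pd.DataFrame:
    """Mean profile per (bioreactor, phase) — the experimental unit for
    the phase statistics, which average out repeated daily sampling."""
    value_cols = list(value_cols) if value_cols is not None else list(profiles.columns)
    joined = profiles.join(meta[["bioreactor", "phase"]], how="inner")
    if len(joined) != len(profiles):
        missing = sorted(set(profiles.index) - set(meta.index))
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return joined.groupby(["bioreactor", "phase"], observed=True)[value_cols].mean()


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc rank comparison with tie correction.

    For each pair of groups, ``z = (Rbar_i - Rbar_j) / sqrt(V)`` with
    ``V = (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` where
    ``T = sum(t^3 - t)`` over tie groups; two-sided normal p-values.
    """
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n_total = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        var = base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        z = (mean_ranks[g1] - mean_ranks[g2]) / math.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((g1, g2, z, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


def phase_species_stats(
    profiles: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis + Dunn phase statistics on per-bioreactor means.

    ``profiles`` is samples x species (e.g. from
    :func:`community_profile`); ``meta`` maps sample_id to bioreactor
    and phase.  Returns ``(kw, dunn)``: the tie-corrected KW H and p per
    species across phases, and the Dunn pairwise table with
    BH-adjusted p-values (adjusted within each species' family of phase
    pairs).
    """
    means = bioreactor_phase_means(profiles, meta)
    phase_level = means.index.get_level_values("phase")
    present = [p for p in PHASES if p in set(phase_level)]
    if len(present) < 2:
        raise ValueError("need at least 2 phases for phase statistics")
    for p in present:
        if (phase_level == p).sum() < 2:
            raise ValueError(f"phase {p!r} has fewer than 2 bioreactor means")

    kw_rows, dunn_frames = [], []
    for species in means.columns:
        groups = {p: means.loc[phase_level == p, species].to_numpy() for p in present}
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0:  # scipy.kruskal rejects all-identical input
            h, p_kw = 0.0, 1.0
        else:
            h, p_kw = stats.kruskal(*groups.values())
        kw_rows.append((species, float(h), float(p_kw)))
        pairs = dunn_test(groups)
        pairs.insert(0, "species", species)
        pairs["p_adj"] = adjust_pvalues(pairs["p_raw"].to_numpy(), "bh")
        dunn_frames.append(pairs)
    kw = pd.DataFrame(kw_rows, columns=["species", "H", "p_raw"])
    return kw, pd.concat(dunn_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pathway profiling
# ---------------------------------------------------------------------------

@dataclass
class PathwayMap:
    """Full pathway membership (for coverage denominators) plus the KO
    assignment of the observed protein groups."""

    pathway_to_kos: dict[str, frozenset]
    ko_to_protein_groups: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, kos in self.pathway_to_kos.items() if not kos]
        if empty:
            raise ValueError(f"pathways with zero KOs: {empty}")


@dataclass
class PathwayProfile:
    """Coverage-filtered samples x pathways intensity matrix."""

    matrix: pd.DataFrame            # samples x retained pathways (summed intensity)
    sample_totals: pd.Series        # per-sample total KO-assigned intensity
    meta: pd.DataFrame              # sample_id -> bioreactor, phase
    coverage: pd.DataFrame          # per-pathway coverage, protein count, retained flag + reason

    @property
    def relative(self) -> pd.DataFrame:
        """Pathway intensity relative to total KO-assigned intensity."""
        return self.matrix.div(self.sample_totals, axis=0)


def pathway_profile(
    table: pd.DataFrame,
    pathway_map: PathwayMap,
    min_coverage: float = 0.15,
    min_proteins: int = 5,
) -> PathwayProfile:
    """Aggregate protein intensities into retained KEGG pathways.

    A protein group contributes to every pathway containing its KO (no
    intensity splitting).  Coverage is the fraction of a pathway's KOs
    detected anywhere in the table; pathways below ``min_coverage`` or
    with fewer than ``min_proteins`` distinct detected protein groups
    are excluded and listed with the failing filter.
    """
    validate_protein_table(table)
    if "ko" not in table.columns or table["ko"].fillna("").eq("").all():
        raise ValueError("pathway profiling requires KO annotations on at least one protein group")
    annotated = table[table["ko"].notna() & (table["ko"] != "")]
    detected_kos = set(annotated["ko"])

    meta = annotated.groupby("sample_id", observed=True)[["bioreactor", "phase"]].first()
    sample_totals = annotated.groupby("sample_id", observed=True)["intensity"].sum()

    cov_rows, columns = [], {}
    for pathway, kos in pathway_map.pathway_to_kos.items():
        hit_kos = detected_kos & kos
        coverage = len(hit_kos) / len(kos)
        rows = annotated[annotated["ko"].isin(hit_kos)]
        n_proteins = rows["protein_group"].nunique()
        if coverage < min_coverage:
            reason = "coverage"
        elif n_proteins < min_proteins:
            reason = "protein_count"
        else:
            reason = ""
            columns[pathway] = rows.groupby("sample_id", observed=True)["intensity"].sum()
        cov_rows.append((pathway, len(kos), len(hit_kos), coverage, n_proteins, reason == "", reason))

    coverage_report = pd.DataFrame(
        cov_rows,
        columns=["pathway", "n_kos", "n_detected_kos", "coverage", "n_proteins", "retained", "excluded_reason"],
    )
    matrix = pd.DataFrame(columns, index=sample_totals.index).fillna(0.0)
    return PathwayProfile(matrix=matrix, sample_totals=sample_totals, meta=meta, coverage=coverage_report)


def phase_log2fc(
    profile: PathwayProfile,
    phase_a: str = "stabilization",
    phase_b: str = "exposure",
    fc_threshold: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway Log2FC of mean relative intensity (B over A) with a
    Kruskal-Wallis phase test and the combined retention flag.

    ``retained`` is true iff ``|Log2FC| >= fc_threshold`` and the KW p
    is below ``alpha``; a zero phase mean yields a missing fold change
    (flagged, never +/- infinity).
    """
    phases = profile.meta["phase"]
    in_a = phases == phase_a
    in_b = phases == phase_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("both phases need at least 2 samples")
    rel = profile.relative
    rows = []
    for pathway in rel.columns:
        xa = rel.loc[in_a[in_a].index, pathway].to_numpy()
        xb = rel.loc[in_b[in_b].index, pathway].to_numpy()
        mean_a, mean_b = xa.mean(), xb.mean()
        if mean_a <= 0 or mean_b <= 0:
            log2fc = float("nan")
        else:
            log2fc = float(np.log2(mean_b / mean_a))
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p_kw = 1.0
        else:
            _, p_kw = stats.kruskal(xa, xb)
        retained = bool(not np.isnan(log2fc) and abs(log2fc) >= fc_threshold and p_kw < alpha)
        if np.isnan(log2fc) or log2fc == 0:
            direction = ""
        else:
            direction = "up" if log2fc > 0 else "down"
        rows.append((pathway, log2fc, float(p_kw), retained, direction, np.isnan(log2fc)))
    return pd.DataFrame(
        rows, columns=["pathway", "log2fc", "p_kw", "retained", "direction", "undefined_fc"]
    )


# ---------------------------------------------------------------------------
# ordination statistics
# ---------------------------------------------------------------------------

def bray_curtis(matrix) -> np.ndarray:
    """Symmetric Bray-Curtis dissimilarity matrix of non-negative profiles."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        sample = int(np.argmax(row_sums == 0))
        raise ValueError(f"all-zero sample at row {sample}")
    return squareform(pdist(x, metric="braycurtis"))


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    uniq = np.unique(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = len(uniq) - 1
    df_within = n - len(uniq)
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dist_matrix, group_labels, n_perm: int = 999, seed: int = 0
) -> dict:
    """One-way PERMANOVA pseudo-F with a label-permutation p-value.

    ``F = (SS_between/(g-1)) / (SS_within/(N-g))`` on squared
    dissimilarities; ``p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)``.
    """
    d = np.asarray(dist_matrix, dtype=float)
    labels = np.asarray(group_labels)
    if d.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix and labels disagree in size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups of size 1 are not testable: {list(small)}")
    d2 = d**2
    f_obs = _permanova_f(d2, labels)
    rng = substream(seed, "permanova", *uniq)
    count = 0
    for _ in range(n_perm):
        count += _permanova_f(d2, rng.permutation(labels)) >= f_obs
    p = (count + 1) / (n_perm + 1)
    return {"pseudo_f": float(f_obs), "p": float(p), "n_perm": n_perm, "n": len(labels)}


def pairwise_permanova(
    dist_matrix, group_labels, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """All pairwise PERMANOVA comparisons, Hochberg-adjusted."""
    d = np.asarray(dist_matrix, dtype=float)
    labels = np.asarray(group_labels)
    rows = []
    for g1, g2 in itertools.combinations(np.unique(labels), 2):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        res = permanova(d[np.ix_(idx, idx)], labels[idx], n_perm=n_perm, seed=seed)
        rows.append((g1, g2, res["pseudo_f"], res["p"]))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_f", "p_raw"])
    out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), "hochberg")
    return out


def ordinate(matrix) -> dict:
    """Column-centered PCA via singular value decomposition.

    Returns sample scores, feature loadings and explained-variance
    fractions (non-increasing, summing to <= 1).  Component signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var == 0:
        k = min(x.shape)
        return {
            "scores": np.zeros((x.shape[0], k)),
            "loadings": np.zeros((x.shape[1], k)),
            "explained": np.zeros(k),
        }
    # deterministic sign: largest-magnitude loading positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = u * s * flip
    explained = (s**2 / (x.shape[0] - 1)) / total_var
    return {"scores": scores, "loadings": vt.T, "explained": explained}


# ---------------------------------------------------------------------------
# exposure-design arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseSpec:
    """Anchors the bioreactor concentration to a fraction of the ADI.

    Defaults reproduce the azoxystrobin design: ADI 0.2 mg/kg bw/day,
    10% of ADI, 70 kg adult, one 250 ml daily medium-exchange volume,
    molar mass 403.4 g/mol.
    """

    adi: float = 0.2                 # mg per kg body weight per day
    fraction_of_adi: float = 0.10
    body_weight: float = 70.0        # kg
    reactor_volume: float = 250.0    # ml exchanged per day
    molar_mass: float = 403.4        # g/mol

    def __post_init__(self) -> None:
        for name in ("adi", "body_weight", "reactor_volume", "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.fraction_of_adi <= 1:
            raise ValueError("fraction_of_adi must be in (0, 1]")


@dataclass(frozen=True)
class DoseResult:
    mg_per_ml: float
    micromolar: float

    @property
    def printed_micromolar(self) -> float:
        """µM truncated to one decimal, the precision used in reporting."""
        return math.floor(self.micromolar * 10) / 10


def bioreactor_dose(spec: DoseSpec | None = None) -> DoseResult:
    """Daily dose concentration for the continuous bioreactor.

    ``daily mass = ADI x fraction x body weight`` spread over one daily
    medium-exchange volume; mg/ml equals g/l, so the molar concentration
    is ``(mg/ml) / molar_mass * 1e6`` µM.
    """
    s = spec or DoseSpec()
    daily_mass_mg = s.adi * s.fraction_of_adi * s.body_weight
    mg_per_ml = daily_mass_mg / s.reactor_volume
    micromolar = mg_per_ml / s.molar_mass * 1e6
    return DoseResult(mg_per_ml=mg_per_ml, micromolar=micromolar)


@dataclass(frozen=True)
class ExposureDesign:
    """Enumerators of the larval exposure design and bioreactor inoculum."""

    n_colonization_statuses: int = 2   # microbiome-depleted, SIHUMIx-inoculated
    n_exposure_groups: int = 3         # vehicle + two azoxystrobin concentrations
    flasks_per_group: int = 10
    embryos_per_flask: int = 30
    n_strains: int = 8
    cells_per_strain: float = 1e9

    @property
    def total_flasks(self) -> int:
        return self.n_colonization_statuses * self.n_exposure_groups * self.flasks_per_group

    @property
    def flasks_per_status(self) -> int:
        return self.n_exposure_groups * self.flasks_per_group

    @property
    def inoculum_cells(self) -> float:
        return self.n_strains * self.cells_per_strain
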