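"""Synthetic cohort generator.

Produces the three input tables the analysis pipelines consume — a wide
log2 protein-intensity matrix with intensity-dependent (MNAR)
missingness, a long glycopeptide quant table with retention times and
AUC areas, and a sample metadata table — together with a ground-truth
record of every injected effect, so that parameter-recovery and
null-calibration tests need no external data.

Site-specific metric effects are injected by exponentially tilting each
site's glycoform profile so that the abundance-weighted degree equals the
configured per-group target in expectation; the tilt exponents are solved
numerically and validated against the achievable range of the site's
glycoform panel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from glycodiff.glycans import GlycanClass, derive_features, parse_composition

GRADE_ORDER = ["Normal", "G1", "G2", "G3"]
GLEASON_ORDER = ["GG2", "GG3", "GG4", "GG5"]
METRICS = ("fucosylation", "sialylation", "galactosylation")

#: Glycoform panel assigned to every effect-carrying site: spans the full
#: [0, 1] range of each metric so any target degree is feasible.
VERSATILE_PANEL = ["N4H5", "N4H5F1", "N4H5S1", "N4H5S2", "N4H5F1S2",
                   "N4H4F1", "N4H3"]


class ConfigError(ValueError):
    """Invalid or infeasible cohort configuration."""


@dataclass(frozen=True)
class ProteinEffect:
    """Additive log2 shift of one protein's abundance per group."""

    protein: str
    log2_shift: dict[str, float]


@dataclass(frozen=True)
class SiteEffect:
    """Target metric degrees of one glycosite per group.

    ``targets`` maps metric name -> group -> target degree in [0, 1];
    groups not listed keep the site's baseline profile.
    """

    protein: str
    glycosite: str
    targets: dict[str, dict[str, float]]


@dataclass
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"Normal": 46, "G1": 9, "G2": 16, "G3": 24})
    gleason_sizes: dict[str, int] = field(
        default_factory=lambda: {"GG2": 7, "GG3": 12, "GG4": 15, "GG5": 15})
    n_proteins: int = 653
    n_glycoproteins: int = 22
    n_glycosites: int = 29
    n_glycans: int = 53
    n_glycopeptides: int = 145
    # protein matrix (log2 scale)
    base_mean: float = 25.0
    base_sd: float = 2.0
    noise_sd: float = 0.5
    mnar_enabled: bool = True
    mnar_threshold_shift: float = -1.5   # threshold = base_mean + shift * base_sd
    mnar_scale: float = 1.0
    # glycopeptide table
    rt_jitter: float = 0.1
    rt_outlier_rate: float = 0.01
    site_log_abundance_mean: float = 11.5   # natural-log AUC of a site total
    site_log_abundance_sd: float = 0.8
    effect_site_log_boost: float = 2.0      # keep spiked sites clear of the AUC floor
    auc_noise_sd: float = 0.1               # per-record lognormal sigma
    dirichlet_concentration: float = 150.0
    dropout_rate: float = 0.02
    # effects
    protein_effects: list[ProteinEffect] = field(default_factory=list)
    site_effects: list[SiteEffect] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {name} needs >= 2 samples, got {n}")
        n_cancer = sum(n for g, n in self.group_sizes.items() if g != "Normal")
        if sum(self.gleason_sizes.values()) != n_cancer:
            raise ConfigError(
                f"gleason sizes sum to {sum(self.gleason_sizes.values())}, "
                f"but there are {n_cancer} cancer samples")
        for p in (self.rt_outlier_rate, self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if len(self.site_effects) > self.n_glycosites:
            raise ConfigError("more site effects than glycosites")
        for eff in self.site_effects:
            for metric, per_group in eff.targets.items():
                if metric not in METRICS:
                    raise ConfigError(f"unknown metric {metric!r}")
                for group, t in per_group.items():
                    if group not in self.group_sizes:
                        raise ConfigError(f"unknown group {group!r} in site effect")
                    if not 0.0 <= t <= 1.0:
                        raise ConfigError(
                            f"target {metric}={t} for {eff.protein} "
                            f"{eff.glycosite} outside [0, 1]")
        if self.n_glycopeptides < self.n_glycosites:
            raise ConfigError("need at least one glycopeptide per glycosite")
        if self.n_glycopeptides < self.n_glycans:
            raise ConfigError("cannot use every glycan with fewer glycopeptides")


@dataclass
class GroundTruth:
    """Record of injected effects, for recovery tests."""

    protein_effects: list[ProteinEffect]
    site_effects: list[SiteEffect]
    rt_outliers: pd.DataFrame   # sample_id, protein, glycosite, glycan
    site_glycans: dict[tuple[str, str], list[str]]

    def to_json(self) -> str:
        payload = {
            "protein_effects": [dataclasses.asdict(e) for e in self.protein_effects],
            "site_effects": [dataclasses.asdict(e) for e in self.site_effects],
            "rt_outliers": self.rt_outliers.to_dict(orient="records"),
            "site_glycans": {f"{p}|{s}": g for (p, s), g in self.site_glycans.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# glycan library


def enumerate_glycan_library() -> list[str]:
    """All composition strings over N 2-6, H 3-9, F 0-1, S 0..antennae."""
    out = []
    for n in range(2, 7):
        for h in range(3, 10):
            for f in (0, 1):
                base = parse_composition(f"N{n}H{h}" + (f"F{f}" if f else ""))
                max_s = derive_features(base).antennae
                for s in range(0, max_s + 1):
                    comp = dataclasses.replace(base, S=s)
                    if derive_features(comp).glycan_class is GlycanClass.OLIGOMANNOSE \
                            and (f or s):
                        continue  # unreachable, oligomannose requires F=S=0
                    out.append(comp.render())
    return sorted(set(out))


def _sample_glycan_library(n_glycans: int, rng: np.random.Generator) -> list[str]:
    """Sample a library covering every glycan class, panel included."""
    pool = enumerate_glycan_library()
    chosen = list(VERSATILE_PANEL)
    by_class: dict[GlycanClass, list[str]] = {}
    for g in pool:
        by_class.setdefault(derive_features(parse_composition(g)).glycan_class, []).append(g)
    for cls, members in sorted(by_class.items(), key=lambda kv: kv[0].value):
        if not any(g in members for g in chosen):
            chosen.append(members[int(rng.integers(len(members)))])
    if n_glycans < len(chosen):
        raise ConfigError(f"n_glycans={n_glycans} too small to cover all classes "
                          f"and the effect panel ({len(chosen)} needed)")
    remaining = [g for g in pool if g not in chosen]
    extra = rng.choice(len(remaining), size=n_glycans - len(chosen), replace=False)
    chosen += [remaining[i] for i in sorted(extra)]
    return chosen


# ---------------------------------------------------------------------------
# profile tilting


def _metric_ratios(glycans: list[str], metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-glycoform (numerator, denominator) contributions of a metric."""
    feats = [derive_features(parse_composition(g)) for g in glycans]
    if metric == "fucosylation":
        num = np.array([float(f.is_fucosylated) for f in feats])
        den = np.ones(len(feats))
    elif metric == "sialylation":
        num = np.array([float(f.sialic_antennae) for f in feats])
        den = np.array([float(f.antennae) for f in feats])
    elif metric == "galactosylation":
        num = np.array([
            float(f.galactoses) if f.glycan_class is GlycanClass.COMPLEX else 0.0
            for f in feats])
        den = np.array([
            float(f.antennae) if f.glycan_class is GlycanClass.COMPLEX else 0.0
            for f in feats])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return num, den


def realized_degree(weights: np.ndarray, glycans: list[str], metric: str) -> float:
    num, den = _metric_ratios(glycans, metric)
    d = float(np.dot(weights, den))
    return float(np.dot(weights, num) / d) if d > 0 else float("nan")


def tilt_profile(
    base: np.ndarray, glycans: list[str], targets: dict[str, float]
) -> np.ndarray:
    """Exponentially reweight ``base`` so each metric degree hits its target.

    Weight of glycoform i becomes ``base_i * exp(sum_m lambda_m * x_mi)``
    with ``x_mi`` the glycoform's per-antenna (or binary) metric ratio;
    the exponents are solved so every targeted abundance-weighted degree
    equals its target. Raises :class:`ConfigError` for targets outside the
    achievable range of the panel.
    """
    metrics = sorted(targets)
    ratios = []
    for m in metrics:
        num, den = _metric_ratios(glycans, m)
        x = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        active = den > 0
        lo = x[active].min() if active.any() else 0.0
        hi = x[active].max() if active.any() else 0.0
        t = targets[m]
        if not lo <= t <= hi or not active.any():
            raise ConfigError(
                f"{m} target {t} infeasible for panel {glycans} "
                f"(achievable range [{lo}, {hi}])")
        ratios.append((num, den, x))

    def residual(lam: np.ndarray) -> np.ndarray:
        tilt = np.zeros(len(glycans))
        for k, (_, _, x) in enumerate(ratios):
            tilt += lam[k] * x
        w = base * np.exp(np.clip(tilt, -60, 60))
        w = w / w.sum()
        res = []
        for k, (num, den, _) in enumerate(ratios):
            d = np.dot(w, den)
            res.append(np.dot(w, num) / d - targets[metrics[k]])
        return np.array(res)

    sol = optimize.least_squares(residual, x0=np.zeros(len(metrics)),
                                 bounds=(-60, 60), xtol=1e-14, ftol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ConfigError(
            f"could not tilt profile to targets {targets} on panel {glycans} "
            f"(residual {sol.fun})")
    tilt = np.zeros(len(glycans))
    for k, (_, _, x) in enumerate(ratios):
        tilt += sol.x[k] * x
    w = base * np.exp(np.clip(tilt, -60, 60))
    return w / w.sum()


# ---------------------------------------------------------------------------
# cohort generation


def _make_metadata(config: CohortConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for grade in GRADE_ORDER:
        for _ in range(config.group_sizes.get(grade, 0)):
            i += 1
            rows.append({"sample_id": f"S{i:03d}", "grade": grade, "gleason": "NA"})
    meta = pd.DataFrame(rows)
    cancer_idx = meta.index[meta["grade"] != "Normal"]
    labels = []
    for gg in GLEASON_ORDER:
        labels += [gg] * config.gleason_sizes.get(gg, 0)
    meta.loc[cancer_idx, "gleason"] = labels
    return meta


def _make_sites(config: CohortConfig, rng: np.random.Generator):
    """Glycosite list: effect sites keep their configured names."""
    sites = [(e.protein, e.glycosite) for e in config.site_effects]
    seen_proteins = {p for p, _ in sites}
    proteins = list(dict.fromkeys(
        [p for p, _ in sites]
        + [f"GPROT{i:02d}" for i in range(1, config.n_glycoproteins + 1)]
    ))[:config.n_glycoproteins]
    if len(proteins) < len(seen_proteins):
        raise ConfigError("more effect glycoproteins than n_glycoproteins")
    # one site per protein first, then distribute the rest round-robin
    positions = rng.choice(np.arange(40, 900), size=config.n_glycosites * 3,
                           replace=False)
    pos_iter = iter(int(p) for p in positions)
    taken = {s for s in sites}
    for p in proteins:
        if len(sites) >= config.n_glycosites:
            break
        if p not in {q for q, _ in sites}:
            sites.append((p, f"N{next(pos_iter)}"))
    j = 0
    while len(sites) < config.n_glycosites:
        p = proteins[j % len(proteins)]
        cand = (p, f"N{next(pos_iter)}")
        if cand not in taken:
            sites.append(cand)
            taken.add(cand)
        j += 1
    return sites


def _assign_glycans(config: CohortConfig, sites, library, rng) -> dict:
    """Choose each site's glycoform panel; every library glycan gets used."""
    effect_sites = {(e.protein, e.glycosite) for e in config.site_effects}
    n_sites = len(sites)
    slots = config.n_glycopeptides - len(effect_sites) * len(VERSATILE_PANEL)
    plain_sites = [s for s in sites if s not in effect_sites]
    usage = {g: 0 for g in library}
    for g in VERSATILE_PANEL:
        usage[g] += len(effect_sites)
    assignment: dict[tuple[str, str], list[str]] = {
        s: list(VERSATILE_PANEL) for s in effect_sites}
    if not plain_sites:
        if slots != 0:
            raise ConfigError(
                "n_glycopeptides does not match the effect-site panels")
        return assignment
    if slots < len(plain_sites):
        raise ConfigError("not enough glycopeptides for one glycoform per site")
    base = slots // len(plain_sites)
    rem = slots - base * len(plain_sites)
    order = rng.permutation(len(plain_sites))
    for rank, si in enumerate(order):
        site = plain_sites[si]
        q = base + (1 if rank < rem else 0)
        tiebreak = rng.permutation(len(library))
        ranked = sorted(range(len(library)),
                        key=lambda i: (usage[library[i]], tiebreak[i]))
        panel = [library[i] for i in ranked[:q]]
        for g in panel:
            usage[g] += 1
        assignment[site] = panel
    return assignment


def generate_cohort(config: CohortConfig):
    """Generate one synthetic cohort.

    Returns ``(protein_df, glyco_df, metadata_df, ground_truth)`` where
    ``protein_df`` is proteins x samples (log2, NaN = missing),
    ``glyco_df`` is the long quant table and ``metadata_df`` the sample
    sheet. Deterministic for a fixed config (including seed).
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_struct, rng_prot, rng_glyco, rng_rt = (np.random.default_rng(s) for s in seeds)

    meta = _make_metadata(config)
    samples = meta["sample_id"].tolist()
    grades = meta.set_index("sample_id")["grade"]

    # ---- protein matrix -------------------------------------------------
    protein_names = [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]
    name_to_row = {p: i for i, p in enumerate(protein_names)}
    effects = np.zeros((config.n_proteins, len(samples)))
    for eff in config.protein_effects:
        if eff.protein not in name_to_row:
            raise ConfigError(f"unknown protein {eff.protein!r} in effect list")
        for j, s in enumerate(samples):
            effects[name_to_row[eff.protein], j] = eff.log2_shift.get(grades[s], 0.0)
    baseline = rng_prot.normal(config.base_mean, config.base_sd, size=config.n_proteins)
    values = (baseline[:, None] + effects
              + rng_prot.normal(0.0, config.noise_sd,
                                size=(config.n_proteins, len(samples))))
    if config.mnar_enabled:
        threshold = config.base_mean + config.mnar_threshold_shift * config.base_sd
        p_missing = 1.0 / (1.0 + np.exp((values - threshold) / config.mnar_scale))
        missing = rng_prot.random(values.shape) < p_missing
        values = np.where(missing, np.nan, values)
    protein_df = pd.DataFrame(values, index=pd.Index(protein_names, name="protein"),
                              columns=samples)

    # ---- glycopeptide table ---------------------------------------------
    library = _sample_glycan_library(config.n_glycans, rng_struct)
    sites = _make_sites(config, rng_struct)
    site_glycans = _assign_glycans(config, sites, library, rng_struct)
    effect_lookup = {(e.protein, e.glycosite): e for e in config.site_effects}

    # per-glycopeptide RT centers
    rt_center = {}
    for site, glycans in site_glycans.items():
        for g in glycans:
            rt_center[(site[0], site[1], g)] = float(rng_rt.uniform(15.0, 100.0))

    records = []
    outlier_records = []
    for site in sites:
        glycans = site_glycans[site]
        k = len(glycans)
        base_profile = rng_glyco.dirichlet(np.full(k, 5.0))
        eff = effect_lookup.get(site)
        profiles = {}
        for grade in GRADE_ORDER:
            if eff is None:
                profiles[grade] = base_profile
            else:
                targets = {m: per_group[grade]
                           for m, per_group in eff.targets.items()
                           if grade in per_group}
                profiles[grade] = (tilt_profile(base_profile, glycans, targets)
                                   if targets else base_profile)
        log_mean = config.site_log_abundance_mean + (
            config.effect_site_log_boost if eff is not None else 0.0)
        for s in samples:
            grade = grades[s]
            total = float(np.exp(rng_glyco.normal(log_mean,
                                                  config.site_log_abundance_sd)))
            alpha = np.maximum(config.dirichlet_concentration * profiles[grade], 1e-3)
            shares = rng_glyco.dirichlet(alpha)
            noise = np.exp(rng_glyco.normal(0.0, config.auc_noise_sd, size=k))
            dropout = rng_glyco.random(k) < config.dropout_rate
            is_outlier = rng_rt.random(k) < config.rt_outlier_rate
            rt_noise = rng_rt.normal(0.0, config.rt_jitter, size=k)
            shift_mag = rng_rt.uniform(8.0, 25.0, size=k)
            shift_sign = np.where(rng_rt.random(k) < 0.5, -1.0, 1.0)
            for i, g in enumerate(glycans):
                if dropout[i]:
                    continue
                auc = total * shares[i] * noise[i]
                rt = rt_center[(site[0], site[1], g)] + rt_noise[i]
                if is_outlier[i]:
                    rt = max(rt + shift_sign[i] * shift_mag[i], 1.0)
                    outlier_records.append({
                        "sample_id": s, "protein": site[0],
                        "glycosite": site[1], "glycan": g})
                records.append({
                    "sample_id": s, "protein": site[0], "glycosite": site[1],
                    "glycan": g, "rt": round(rt, 4), "auc": round(auc, 4)})
    glyco_df = pd.DataFrame(records,
                            columns=["sample_id", "protein", "glycosite",
                                     "glycan", "rt", "auc"])
    truth = GroundTruth(
        protein_effects=list(config.protein_effects),
        site_effects=list(config.site_effects),
        rt_outliers=pd.DataFrame(outlier_records,
                                 columns=["sample_id", "protein",
                                          "glycosite", "glycan"]),
        site_glycans=site_glycans,
    )
    return protein_df, glyco_df, meta, truth


def write_cohort(directory, protein_df, glyco_df, meta, truth: GroundTruth) -> None:
    """Write the three TSVs plus the ground-truth JSON to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    protein_df.to_csv(d / "proteins.tsv", sep="\t", lineterminator="\n")
    glyco_df.to_csv(d / "glycopeptides.tsv", sep="\t", index=False, lineterminator="\n")
    meta.to_csv(d / "metadata.tsv", sep="\t", index=False, lineterminator="\n")
    (d / "ground_truth.json").write_text(truth.to_json())


# ---------------------------------------------------------------------------
# presets


def _paper_like_effects() -> tuple[list[ProteinEffect], list[SiteEffect]]:
    up = [ProteinEffect(f"P{i:04d}", {"G1": 0.5, "G2": 1.0, "G3": 1.5})
          for i in range(1, 41)]
    down = [ProteinEffect(f"P{i:04d}", {"G1": -0.5, "G2": -1.0, "G3": -1.5})
            for i in range(41, 76)]
    cancer = ("G1", "G2", "G3")

    def flat(metric: str, normal: float, pca: float) -> dict:
        return {metric: {"Normal": normal, **{g: pca for g in cancer}}}

    sites = [
        SiteEffect("PPAP", "N94", flat("fucosylation", 0.47, 0.83)),
        SiteEffect("POSTN", "N599", {
            **flat("fucosylation", 0.24, 0.72),
            **flat("sialylation", 0.83, 0.44),
        }),
        SiteEffect("THRB", "N121", flat("sialylation", 0.50, 0.25)),
        SiteEffect("CO6A2", "N785", flat("sialylation", 0.20, 0.50)),
        SiteEffect("IGG1", "N299", flat("galactosylation", 0.60, 0.54)),
        SiteEffect("MFAP4", "N87", flat("sialylation", 0.50, 0.35)),
    ]
    return up + down, sites


def scenario_presets() -> dict[str, CohortConfig]:
    """Named cohort configurations.

    - ``null``: study-sized cohort with no injected effects.
    - ``paper-like``: 40 up- and 35 down-shifted proteins plus six
      glycosites with metric shifts in the directions of the motivating
      study.
    - ``minimal``: tiny cohort for fast smoke tests.
    """
    prot_eff, site_eff = _paper_like_effects()
    return {
        "null": CohortConfig(),
        "paper-like": CohortConfig(protein_effects=prot_eff, site_effects=site_eff),
        "minimal": CohortConfig(
            group_sizes={"Normal": 5, "G1": 5, "G2": 5, "G3": 5},
            gleason_sizes={"GG2": 4, "GG3": 4, "GG4": 4, "GG5": 3},
            n_proteins=20, n_glycoproteins=4, n_glycosites=5,
            n_glycans=10, n_glycopeptides=14,
            protein_effects=[ProteinEffect("P0001", {"G1": 1.0, "G2": 1.5, "G3": 2.0})],
            site_effects=[SiteEffect("PPAP", "N94",
                                     {"fucosylation": {"Normal": 0.3, "G1": 0.7,
                                                       "G2": 0.7, "G3": 0.7}})],
        ),
    }
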