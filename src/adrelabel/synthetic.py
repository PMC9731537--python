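"""Synthetic cohort generator.

Emulates the statistical structure of a baseline ADNI-style table: 559
participants described by 224 features (7 sociodemographic / medical
history, 40 cognitive and functional assessment scores, 177 regional
tau-PET/MRI uptake values), a three-class clinical diagnosis (CN / MCI /
AD), and a held-out CSF amyloid-beta biomarker.

The cohort is built from five latent clusters — a male-only cluster, a
female-only cluster, a younger cluster with strong parental family
history, an AD-like cluster with elevated tau uptake and depressed
memory scores, and a mixed "catchall" cluster with intermediate
pathology.  Observed diagnoses are planted so that the AD-like cluster
contains a configurable fraction of CN/MCI labels whose *latent* truth
is AD (the targets a downstream re-labelling rule should recover), and a
configurable number of AD labels fall outside that cluster (cases the
rule must leave untouched).  The amyloid biomarker decreases with
pathology severity and is never part of the clustering features.

All sampling flows through one ``numpy.random.Generator`` so a config
plus a seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import ClusterAssignment, FeatureTable, LabelSet

__all__ = [
    "AbetaParams",
    "ClusterSpec",
    "ConfigurationError",
    "SyntheticConfig",
    "SyntheticDataset",
    "default_cluster_spec",
    "strong_effect_config",
    "generate_dataset",
    "inject_missingness",
]


class ConfigurationError(ValueError):
    """Inconsistent or out-of-range generator configuration."""


# Tau-sensitive Desikan-Killiany-style regions listed first; the AD-like
# cluster's uptake shift is applied to the first ``n_tau_marker`` imaging
# columns, so these are the regions that carry the pathology signal.
_DK_REGIONS = [
    "inferiorparietal", "middletemporal", "lateraloccipital", "entorhinal",
    "inferiortemporal", "fusiform", "precuneus", "superiortemporal",
    "supramarginal", "parahippocampal", "posteriorcingulate", "isthmuscingulate",
    "lingual", "superiorparietal", "bankssts", "temporalpole",
    "transversetemporal", "insula", "caudalanteriorcingulate",
    "caudalmiddlefrontal", "cuneus", "frontalpole", "lateralorbitofrontal",
    "medialorbitofrontal", "paracentral", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "precentral",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
]
_SUBCORTICAL = [
    "amygdala", "hippocampus", "thalamus", "caudate", "putamen", "pallidum",
    "accumbens", "ventraldc", "cerebellum.cortex", "cerebellum.wm",
    "choroid.plexus", "brainstem.rois", "basal.forebrain", "insula.sub",
    "claustrum", "substantia.nigra", "red.nucleus", "subthalamic",
    "mammillary", "habenula", "globus.med",
]

# CFA scores with hand-set baselines (mean, sd); the first entries are
# memory-loaded composites depressed in the AD-like cluster.
_NAMED_CFA = [
    ("phc_mem", 0.71, 0.45),
    ("lm_immediate", 12.0, 4.0),
    ("lm_delayed", 10.5, 4.5),
    ("mmse_total", 28.0, 2.0),
    ("adas_total", 12.0, 6.0),
    ("cdr_global", 0.3, 0.35),
    ("npi_total", 2.5, 3.5),
    ("gds_total", 1.2, 1.4),
]
N_MEMORY_CFA = 5  # phc_mem .. adas_total carry the memory-depression shift


def imaging_feature_names(n: int) -> list[str]:
    """Desikan-Killiany-flavoured region names, tau-sensitive regions first."""
    names: list[str] = []
    for region in _DK_REGIONS:
        names += [f"ctx.lh.{region}", f"ctx.rh.{region}"]
    for region in _DK_REGIONS:
        names += [f"wm.lh.{region}", f"wm.rh.{region}"]
    for region in _SUBCORTICAL:
        names += [f"lh.{region}", f"rh.{region}"]
    while len(names) < n:
        names.append(f"roi.extra.{len(names)}")
    return names[:n]


@dataclass
class ClusterSpec:
    """Descriptor of one latent cluster.

    ``tau_effect`` and ``memory_effect`` are in units of the feature's
    own standard deviation; ``ad_share``/``mci_share`` weight how AD and
    MCI labels falling outside the AD-like cluster are apportioned.
    """

    name: str
    weight: float
    p_male: float  # 1.0 / 0.0 encode the single-gender constraint
    age_mean: float
    age_sd: float
    edu_mean: float
    edu_sd: float
    fh_rate: float
    apoe4_probs: tuple[float, float, float]
    tau_effect: float = 0.0
    memory_effect: float = 0.0
    abeta_severity: float = 0.0
    ad_like: bool = False
    ad_share: float = 0.0
    mci_share: float = 0.0


def default_cluster_spec() -> list[ClusterSpec]:
    """Five clusters with sizes 50/166/131/131/81 at n=559."""
    return [
        ClusterSpec("AD", 50 / 559, 0.60, 75.1, 9.8, 16.7, 2.5, 0.25,
                    (0.10, 0.40, 0.50), tau_effect=3.0, memory_effect=1.5,
                    ad_like=True),
        ClusterSpec("Catchall-NRF", 166 / 559, 70 / 166, 74.6, 7.2, 16.3, 2.6,
                    0.20, (0.55, 0.35, 0.10), tau_effect=0.6, memory_effect=0.3,
                    abeta_severity=0.40, ad_share=20.0, mci_share=32.0),
        ClusterSpec("Female", 131 / 559, 0.0, 75.9, 8.2, 16.0, 2.4, 0.15,
                    (0.75, 0.20, 0.05), ad_share=7.0, mci_share=28.0),
        ClusterSpec("Male", 131 / 559, 1.0, 78.8, 6.9, 17.1, 2.5, 0.15,
                    (0.75, 0.20, 0.05), ad_share=5.0, mci_share=44.0),
        ClusterSpec("Young-FH", 81 / 559, 35 / 81, 71.3, 6.4, 17.1, 2.1, 0.90,
                    (0.50, 0.35, 0.15), ad_share=1.0, mci_share=15.0),
    ]


@dataclass
class AbetaParams:
    """Exogenous CSF amyloid-beta model: baseline minus slope x severity."""

    mean: float = 1300.0
    sd: float = 300.0
    slope: float = 660.0


@dataclass
class SyntheticConfig:
    n_samples: int = 559
    class_counts: dict = field(
        default_factory=lambda: {"CN": 363, "MCI": 137, "AD": 59}
    )
    n_sociodemo: int = 7
    n_cfa: int = 40
    n_imaging: int = 177
    n_tau_marker: int = 60
    cluster_spec: list = field(default_factory=default_cluster_spec)
    label_noise: float = 24 / 50  # CN/MCI observed labels inside the AD cluster
    noise_cn_fraction: float = 6 / 24  # CN share of the planted noise
    # AD observed labels outside the AD cluster; None derives the count from
    # the class totals (33 under the defaults)
    ad_outside: int | None = None
    missing_rate: float = 0.06
    abeta_params: AbetaParams = field(default_factory=AbetaParams)
    # Pathology-severity multipliers by member role (relative to the AD
    # cluster's tau/memory effect size).
    relabel_severity: float = 0.90
    outside_ad_severity: float = 0.35
    # Cognitive (memory) severity tracks the *observed* diagnosis — the
    # clinician labels by symptoms — while tau tracks the latent cluster
    # role, so labels and biomarkers can disagree.
    mci_memory_severity: float = 0.8
    ad_memory_severity: float = 1.0
    relabel_abeta_severity: float = 1.0
    ad_abeta_severity: float = 0.68
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if any(v < 0 for v in self.class_counts.values()):
            raise ConfigurationError("class counts must be non-negative")
        if sum(self.class_counts.values()) != self.n_samples:
            raise ConfigurationError(
                f"class counts sum to {sum(self.class_counts.values())}, "
                f"expected n_samples={self.n_samples}"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigurationError("label_noise must lie in [0, 1]")
        w = sum(c.weight for c in self.cluster_spec)
        if abs(w - 1.0) > 1e-6:
            raise ConfigurationError(f"cluster weights sum to {w}, expected 1")
        if sum(c.ad_like for c in self.cluster_spec) != 1:
            raise ConfigurationError("exactly one cluster must be AD-like")
        if self.n_sociodemo < 7:
            raise ConfigurationError("n_sociodemo must be >= 7")
        if self.n_cfa < len(_NAMED_CFA):
            raise ConfigurationError(f"n_cfa must be >= {len(_NAMED_CFA)}")
        if self.n_imaging < self.n_tau_marker:
            raise ConfigurationError("n_imaging must be >= n_tau_marker")

    @property
    def n_features(self) -> int:
        return self.n_sociodemo + self.n_cfa + self.n_imaging

    # -- IO ---------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "cluster_spec" in raw:
            raw["cluster_spec"] = [
                ClusterSpec(**{**c, "apoe4_probs": tuple(c["apoe4_probs"])})
                for c in raw["cluster_spec"]
            ]
        if "abeta_params" in raw:
            raw["abeta_params"] = AbetaParams(**raw["abeta_params"])
        return cls(**raw)


def strong_effect_config(seed: int = 0) -> SyntheticConfig:
    """A noiseless, well-separated configuration for recoverability checks.

    Observed labels equal latent labels (no planted noise, no AD cases
    outside the AD cluster), effect sizes are enlarged and categorical
    signatures sharpened so the five latent clusters are unambiguous.
    """
    spec = default_cluster_spec()
    spec[0].tau_effect = 4.0
    spec[0].memory_effect = 2.5
    spec[0].apoe4_probs = (0.0, 0.3, 0.7)
    spec[1].tau_effect = 2.0
    spec[1].memory_effect = 1.0
    spec[1].apoe4_probs = (0.9, 0.1, 0.0)
    spec[2].apoe4_probs = (0.9, 0.1, 0.0)
    spec[3].apoe4_probs = (0.9, 0.1, 0.0)
    spec[4].fh_rate = 1.0
    # family history travels with APoE4 carriership, which sharpens the
    # young-with-family-history cluster against the gender clusters
    spec[4].apoe4_probs = (0.0, 0.9, 0.1)
    spec[4].age_mean, spec[4].age_sd = 68.0, 4.0
    for c in spec[1:]:
        c.fh_rate = c.fh_rate if c is spec[4] else 0.05
    # class counts consistent with all AD labels inside the AD cluster
    return SyntheticConfig(
        cluster_spec=spec,
        label_noise=0.0,
        ad_outside=0,
        missing_rate=0.0,
        class_counts={"CN": 376, "MCI": 133, "AD": 50},
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    table: FeatureTable
    labels: LabelSet           # observed (with planted noise)
    latent_labels: LabelSet    # ground truth
    latent_clusters: ClusterAssignment
    abeta: pd.Series           # exogenous biomarker, never a clustering feature

    def write(self, outdir: str | Path, config: SyntheticConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "features.csv")
        truth = pd.DataFrame(
            {
                "diagnosis": self.labels.labels,
                "latent_diagnosis": self.latent_labels.labels,
                "latent_cluster": self.latent_clusters.assignment,
                "latent_cluster_name": [
                    self.latent_clusters.name_of(c)
                    for c in self.latent_clusters.assignment
                ],
                "csf_abeta": self.abeta,
            }
        )
        truth.to_csv(outdir / "labels.csv", index_label="sample_id")
        if config is not None:
            config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# composition: cluster sizes and per-cluster observed-diagnosis counts
# ---------------------------------------------------------------------------

def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative quotas to integers summing to ``total``."""
    quotas = np.maximum(np.asarray(quotas, dtype=float), 0.0)
    if quotas.sum() == 0:
        quotas = np.ones_like(quotas)
    quotas = quotas * (total / quotas.sum())
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def resolve_composition(config: SyntheticConfig) -> pd.DataFrame:
    """Cluster sizes and observed CN/MCI/AD counts per cluster.

    The AD-like cluster's composition follows ``label_noise`` (fraction
    of its members with a non-AD observed label) and ``noise_cn_fraction``;
    remaining AD labels are apportioned outside by ``ad_share``, remaining
    MCI by ``mci_share``, and CN fills the rest.  Raises when the demands
    cannot be met exactly.
    """
    config.validate()
    specs = config.cluster_spec
    sizes = _largest_remainder(
        np.array([c.weight for c in specs]), config.n_samples
    )
    k = len(specs)
    comp = np.zeros((k, 3), dtype=int)  # columns CN, MCI, AD
    ad_idx = next(i for i, c in enumerate(specs) if c.ad_like)

    noise = int(round(config.label_noise * sizes[ad_idx]))
    cn_in = int(round(config.noise_cn_fraction * noise))
    mci_in = noise - cn_in
    ad_in = sizes[ad_idx] - noise
    comp[ad_idx] = (cn_in, mci_in, ad_in)

    ad_out = config.class_counts["AD"] - ad_in
    if ad_out < 0:
        raise ConfigurationError(
            "AD-cluster size and label_noise imply more in-cluster AD labels "
            f"({ad_in}) than the AD class count ({config.class_counts['AD']})"
        )
    if config.ad_outside is not None and config.ad_outside != ad_out:
        raise ConfigurationError(
            f"ad_outside={config.ad_outside} inconsistent with label_noise "
            f"({ad_in} in-cluster AD labels vs class total "
            f"{config.class_counts['AD']})")

    others = [i for i in range(k) if i != ad_idx]
    comp[others, 2] = _largest_remainder(
        np.array([specs[i].ad_share for i in others]), ad_out
    )
    mci_out = config.class_counts["MCI"] - mci_in
    if mci_out < 0:
        raise ConfigurationError("planted MCI noise exceeds the MCI class count")
    comp[others, 1] = _largest_remainder(
        np.array([specs[i].mci_share for i in others]), mci_out
    )
    for i in others:
        rest = sizes[i] - comp[i, 1] - comp[i, 2]
        if rest < 0:
            raise ConfigurationError(
                f"cluster {specs[i].name!r} too small for its MCI/AD allocation"
            )
        comp[i, 0] = rest
    if comp[:, 0].sum() != config.class_counts["CN"]:
        raise ConfigurationError(
            f"composition yields {comp[:, 0].sum()} CN labels, "
            f"expected {config.class_counts['CN']}"
        )
    return pd.DataFrame(
        comp, columns=["CN", "MCI", "AD"],
        index=[c.name for c in specs],
    ).assign(size=sizes)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _member_severity(config: SyntheticConfig, in_ad_cluster: np.ndarray,
                     observed_ad: np.ndarray) -> np.ndarray:
    """Pathology multiplier per member, relative to the AD cluster's effect.

    In-cluster AD cases carry the full effect; the planted CN/MCI cases in
    the AD cluster (latent AD) a discounted one; AD cases elsewhere a
    slightly smaller one still — so clinically diagnosed AD cases outside
    the AD cluster remain tau-elevated, as real cohorts show.
    """
    sev = np.zeros(len(in_ad_cluster))
    sev[in_ad_cluster & observed_ad] = 1.0
    sev[in_ad_cluster & ~observed_ad] = config.relabel_severity
    sev[~in_ad_cluster & observed_ad] = config.outside_ad_severity
    return sev


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a complete synthetic cohort from ``config``."""
    config = config or SyntheticConfig()
    comp = resolve_composition(config)
    rng = np.random.default_rng(config.seed)
    specs = config.cluster_spec
    k = len(specs)
    n = config.n_samples
    ad_idx = next(i for i, c in enumerate(specs) if c.ad_like)

    # -- cluster membership and observed labels (counts exact by design)
    cluster = np.repeat(np.arange(k), comp["size"].to_numpy())
    diag = np.concatenate([
        np.repeat(["CN", "MCI", "AD"], comp.loc[specs[i].name, ["CN", "MCI", "AD"]])
        for i in range(k)
    ])
    order = rng.permutation(n)  # shuffle so ids carry no structure
    cluster, diag = cluster[order], diag[order]

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    in_ad = cluster == ad_idx
    observed_ad = diag == "AD"
    latent = diag.copy()
    latent[in_ad] = "AD"  # planted CN/MCI inside the AD cluster are truly AD

    # latent-AD roles (in-cluster AD, planted CN/MCI, AD elsewhere) get the
    # AD cluster's effect scaled by their severity; everyone else gets their
    # own cluster's baseline effect
    sev = _member_severity(config, in_ad, observed_ad)
    cluster_tau = np.array([c.tau_effect for c in specs])[cluster]
    cluster_mem = np.array([c.memory_effect for c in specs])[cluster]
    ad_tau, ad_mem = specs[ad_idx].tau_effect, specs[ad_idx].memory_effect
    has_role = sev > 0
    tau_shift = np.where(has_role, ad_tau * sev, cluster_tau)
    diag_mem_sev = np.select(
        [observed_ad, diag == "MCI"],
        [config.ad_memory_severity, config.mci_memory_severity], 0.0)
    mem_shift = np.maximum(ad_mem * diag_mem_sev, cluster_mem)

    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, str] = {}
    kinds: dict[str, str] = {}

    def add(name: str, values: np.ndarray, block: str, kind: str) -> None:
        cols[name], blocks[name], kinds[name] = values, block, kind

    # -- sociodemographic / medical history block
    p_male = np.array([c.p_male for c in specs])[cluster]
    gender = np.where(p_male >= 1.0, 1,
                      np.where(p_male <= 0.0, 0,
                               (rng.random(n) < p_male).astype(int)))
    age = rng.normal(np.array([c.age_mean for c in specs])[cluster],
                     np.array([c.age_sd for c in specs])[cluster])
    edu = np.clip(rng.normal(np.array([c.edu_mean for c in specs])[cluster],
                             np.array([c.edu_sd for c in specs])[cluster]), 6, 24)
    fh_rate = np.array([c.fh_rate for c in specs])[cluster]
    mother_fh = (rng.random(n) < fh_rate).astype(int)
    father_fh = (rng.random(n) < fh_rate * 0.6).astype(int)
    apoe_p = np.array([c.apoe4_probs for c in specs])[cluster]
    u = rng.random(n)
    apoe4 = (u >= apoe_p[:, 0]).astype(int) + (u >= apoe_p[:, 0] + apoe_p[:, 1])
    add("age", age, "sociodemographic", "numeric")
    add("gender", gender, "sociodemographic", "categorical")
    add("education", edu, "sociodemographic", "numeric")
    add("mother_ad_history", mother_fh, "sociodemographic", "categorical")
    add("father_ad_history", father_fh, "sociodemographic", "categorical")
    add("apoe4", apoe4, "sociodemographic", "categorical")
    add("medhist_cardio", (rng.random(n) < 0.3).astype(int),
        "sociodemographic", "categorical")
    for j in range(config.n_sociodemo - 7):
        add(f"medhist_extra_{j}", (rng.random(n) < 0.25).astype(int),
            "sociodemographic", "categorical")

    # -- cognitive / functional assessment block
    named = _NAMED_CFA[: config.n_cfa]
    for idx, (name, mu, sd) in enumerate(named):
        x = rng.normal(mu, sd, size=n)
        if idx < N_MEMORY_CFA:  # memory-loaded scores move with pathology
            direction = 1.0 if name == "adas_total" else -1.0  # error counts rise
            x = x + direction * mem_shift * sd
        add(name, x, "cfa", "numeric")
    for j in range(config.n_cfa - len(named)):
        x = rng.normal(0.0, 1.0, size=n)
        if j < 10:  # assessment sub-items correlate with the composites
            x = x - 0.5 * mem_shift
        add(f"cfa_sub_{j:02d}", x, "cfa", "numeric")

    # -- imaging block: tau SUVR-like values, first n_tau_marker regions
    # carry the pathology elevation
    img_names = imaging_feature_names(config.n_imaging)
    base_sd = 0.2
    for j, name in enumerate(img_names):
        x = rng.normal(1.25, base_sd, size=n)
        if j < config.n_tau_marker:
            x = x + tau_shift * base_sd * rng.normal(1.0, 0.15, size=n)
        add(name, x, "imaging", "numeric")

    df = pd.DataFrame(cols, index=sample_ids)
    table = FeatureTable(df, blocks, kinds)
    if config.missing_rate > 0:
        table = inject_missingness(
            table, config.missing_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    # -- exogenous amyloid biomarker (inverse severity)
    ap = config.abeta_params
    a_sev = np.maximum(
        np.array([c.abeta_severity for c in specs])[cluster],
        np.where(in_ad & ~observed_ad, config.relabel_abeta_severity,
                 np.where(observed_ad, config.ad_abeta_severity, 0.0)),
    )
    abeta = pd.Series(
        rng.normal(ap.mean, ap.sd, size=n) - ap.slope * a_sev,
        index=sample_ids, name="csf_abeta",
    )
    if config.missing_rate > 0:
        mask = rng.random(n) < config.missing_rate
        abeta[mask] = np.nan

    return SyntheticDataset(
        table=table,
        labels=LabelSet(pd.Series(diag, index=sample_ids)),
        latent_labels=LabelSet(pd.Series(latent, index=sample_ids)),
        latent_clusters=ClusterAssignment(
            pd.Series(cluster, index=sample_ids), k=k,
            names={i: c.name for i, c in enumerate(specs)},
        ),
        abeta=abeta,
    )


def inject_missingness(table: FeatureTable, rate: float, seed: int) -> FeatureTable:
    """Mask feature cells completely at random at the given rate.

    Sample ids (the index) are never masked; labels are not part of a
    FeatureTable so they cannot be.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("missing rate must lie in [0, 1]")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.df.shape) < rate
    values = out.df.to_numpy(dtype=float)
    values[mask] = np.nan
    out.df = pd.DataFrame(values, index=out.df.index, columns=out.df.columns)
    return out
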