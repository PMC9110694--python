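"""Synthetic urine-metabolomics cohorts with known ground truth.

Emulates the data structure of a multi-site pregnancy cohort profiled by
untargeted LC-MS: a feature-abundance table (metabolic features x injections,
spectral counts), per-injection metadata, and the generative parameters
(``GroundTruth``) needed for recovery tests.

The generative model is log-normal: for feature *f* and subject *s*,

    log A_fs = baseline_f + slope_f * GA_s + bio_fs

where ``slope_f`` is non-zero only for the informative minority of features
(mixed positive/negative signs), and ``bio_fs`` is per-subject biological
variation. Each injection then multiplies the sample vector by technical
noise, the sample's urine dilution factor, a smooth per-batch injection-order
drift curve, and a small per-site offset. Missingness is left-censoring at a
low abundance quantile, which is what low-value imputation assumes.

Subjects delivering preterm receive inflated biological variation of the
informative features when sampled between weeks 14 and 17 — higher
inter-individual variability in that window, not shifted mean trajectories,
is what degrades GA prediction in preterm pregnancies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_validation_cohort",
    "generate_correlated_blocks",
    "expected_injection_count",
    "write_cohort",
]

#: metadata columns every generated cohort carries
META_COLUMNS = [
    "injection_id",
    "sample_id",
    "subject_id",
    "site",
    "type",
    "batch",
    "injection_order",
    "replicate_group",
    "dilution_level",
    "ga_weeks",
    "ga_delivery_weeks",
    "delivery_group",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study design: 99 discovery subjects (~50%
    destined to deliver preterm), a 20-subject term-only validation cohort,
    GA at collection uniform on 8-19 weeks, four acquisition batches with a
    QC pool injected every 10 positions, 1-4 technical replicates per sample
    (mean ~1.75, i.e. ~172 injections from 99 samples), and 55% of the
    informative features positively associated with GA.
    """

    n_subjects: int = 99
    n_validation: int = 20
    n_features: int = 2000
    n_informative: int = 30
    frac_positive_slope: float = 0.55
    n_batches: int = 4
    qc_every: int = 10
    #: P(1..4 technical replicates); mean 1.75 matches 172 injections / 99 samples
    replicate_distribution: tuple[float, float, float, float] = (0.45, 0.40, 0.10, 0.05)
    ga_range_weeks: tuple[float, float] = (8.0, 19.0)
    frac_preterm: float = 0.5
    #: relative amplitude of the smooth per-batch injection-order drift
    drift_amplitude: float = 0.15
    #: SD of per-sample log dilution factor (urine hydration state)
    dilution_log_sd: float = 0.5
    #: SD of per-injection log technical noise
    noise_log_sd: float = 0.10
    #: SD of per-subject log biological variation
    biological_log_sd: float = 0.30
    #: abundance quantile (of the pre-censoring study distribution) below
    #: which values are censored to missing
    missing_quantile: float = 0.05
    #: features present in blanks at study-like levels (carry-over/contaminants)
    n_contaminants: int = 10
    #: features whose QC dilution-series response is non-linear
    n_dilution_nonlinear: int = 8
    dilution_series_levels: tuple[float, ...] = (0.125, 0.25, 0.5, 0.75, 1.0)
    blanks_per_batch: int = 2
    n_sites: int = 5
    site_log_sd: float = 0.05
    #: blank signal for non-contaminant features, relative to baseline
    blank_epsilon: float = 0.01
    #: inflation of informative-feature biological SD for preterm subjects
    #: sampled inside preterm_window_weeks
    preterm_var_multiplier: float = 2.0
    preterm_window_weeks: tuple[float, float] = (14.0, 17.0)
    slope_range: tuple[float, float] = (0.08, 0.18)
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_validation": self.n_validation,
            "n_features": self.n_features,
            "n_informative": self.n_informative,
            "n_batches": self.n_batches,
            "qc_every": self.qc_every,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0.0 <= self.frac_positive_slope <= 1.0:
            raise ValueError("frac_positive_slope must lie in [0, 1]")
        lo, hi = self.ga_range_weeks
        if not (0.0 < lo < hi < 45.0):
            raise ValueError(f"ga_range_weeks must lie inside (0, 45), got {self.ga_range_weeks}")
        probs = np.asarray(self.replicate_distribution, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("replicate_distribution must be 4 non-negative probabilities summing to 1")
        if len(self.dilution_series_levels) < 3:
            raise ValueError("dilution series needs at least 3 levels")
        extra = self.n_contaminants + self.n_dilution_nonlinear + self.n_informative
        if extra > self.n_features:
            raise ValueError("contaminant/non-linear/informative features exceed n_features")


@dataclass
class GroundTruth:
    """Generative parameters of a simulated cohort, for recovery tests."""

    ga_weeks: dict[str, float]
    delivery_group: dict[str, str]
    informative_feature_ids: list[str]
    slopes: dict[str, float]
    dilution_factors: dict[str, float]
    #: per-batch drift parameterisation: {batch: {"linear": arr, "sine": arr, "phase": float}}
    drift_curves: dict[int, dict]
    baselines: dict[str, float] = field(default_factory=dict)
    contaminant_ids: list[str] = field(default_factory=list)
    dilution_nonlinear_ids: list[str] = field(default_factory=list)
    site_of_subject: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["drift_curves"] = {
            str(b): {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
            for b, d in self.drift_curves.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def expected_injection_count(n_study: int, cfg: SimConfig) -> int:
    """Injections implied by the design: study + blanks + QC pools + dilution series."""
    per_batch = np.array_split(np.arange(n_study), cfg.n_batches)
    n_qc = sum(int(np.ceil(len(b) / cfg.qc_every)) + 1 for b in per_batch)
    return n_study + n_qc + cfg.n_batches * cfg.blanks_per_batch + len(cfg.dilution_series_levels)


def _feature_ids(n: int) -> list[str]:
    half = n // 2
    ids = [f"HILIC_F{i + 1:05d}" for i in range(half)]
    ids += [f"RPLC_F{i + 1:05d}" for i in range(half, n)]
    return ids


def _drift_value(drift: dict, t: np.ndarray | float) -> np.ndarray:
    """Evaluate per-feature multiplicative drift at normalised order t in [0, 1]."""
    lin = np.asarray(drift["linear"])
    sine = np.asarray(drift["sine"])
    t = np.atleast_1d(np.asarray(t, dtype=float))
    # shape (n_features, len(t))
    h = lin[:, None] * (t[None, :] - 0.5) + sine[:, None] * np.sin(np.pi * t[None, :] + drift["phase"])
    return np.exp(drift["amplitude"] * h)


def _simulate_injections(
    cfg: SimConfig,
    rng: np.random.Generator,
    subjects: pd.DataFrame,
    log_subject: np.ndarray,
    baselines: np.ndarray,
    feature_ids: list[str],
    dilution: np.ndarray,
    site_offsets: np.ndarray,
    contaminant_idx: np.ndarray,
    nonlinear_idx: np.ndarray,
    n_batches: int,
    id_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, dict]]:
    """Lay out the injection sequence and compute its abundance matrix."""
    n_feat = len(feature_ids)
    subj_ids = subjects["subject_id"].to_numpy()
    n_subj = len(subj_ids)

    n_reps = rng.choice(np.arange(1, 5), size=n_subj, p=np.asarray(cfg.replicate_distribution))
    study = []  # (subject_index, replicate_number)
    for si in range(n_subj):
        for r in range(int(n_reps[si])):
            study.append((si, r + 1))
    order_perm = rng.permutation(len(study))
    study = [study[i] for i in order_perm]
    batches = np.array_split(np.arange(len(study)), n_batches)

    # equimolar pool of all study samples (true, noise-free)
    pool = np.exp(log_subject).mean(axis=1)

    # shared instrument-sensitivity drift per batch + smaller per-feature deviation
    drift_curves: dict[int, dict] = {}
    for b in range(n_batches):
        lin_common = rng.normal(0.0, 1.0)
        sine_common = rng.normal(0.0, 0.5)
        drift_curves[b + 1] = {
            "amplitude": float(cfg.drift_amplitude),
            "linear": lin_common + rng.normal(0.0, 0.4, size=n_feat),
            "sine": sine_common + rng.normal(0.0, 0.2, size=n_feat),
            "phase": float(rng.uniform(0, np.pi)),
        }

    blank = cfg.blank_epsilon * np.exp(baselines)
    blank[contaminant_idx] = pool[contaminant_idx]

    rows: list[dict] = []
    columns: list[np.ndarray] = []
    qc_counter = 0
    blank_counter = 0
    series_levels = list(cfg.dilution_series_levels)

    def tech_noise() -> np.ndarray:
        return np.exp(rng.normal(0.0, cfg.noise_log_sd, size=n_feat))

    for b, batch_items in enumerate(batches, start=1):
        seq: list[tuple[str, object]] = []
        for j, item_idx in enumerate(batch_items):
            if j % cfg.qc_every == 0:
                seq.append(("qc_pool", None))
            seq.append(("study", study[item_idx]))
        seq.append(("qc_pool", None))
        # blanks at the start and end of the batch, inside the QC brackets
        for k in range(cfg.blanks_per_batch):
            pos = 1 if k % 2 == 0 else len(seq) - 1
            seq.insert(pos, ("blank", None))
        if b == n_batches:
            for level in series_levels:
                seq.append(("qc_dilution", level))

        for order, (kind, info) in enumerate(seq, start=1):
            t = (order - 1) / max(len(seq) - 1, 1)
            g = _drift_value(drift_curves[b], t)[:, 0]
            row = {
                "site": None,
                "type": kind,
                "batch": b,
                "injection_order": order,
                "dilution_level": np.nan,
                "ga_weeks": np.nan,
                "ga_delivery_weeks": np.nan,
                "delivery_group": None,
            }
            if kind == "study":
                si, rep = info
                subj = subjects.iloc[si]
                inj_id = f"{subj.subject_id}_r{rep}"
                values = np.exp(log_subject[:, si]) * tech_noise() * dilution[si]
                values *= site_offsets[:, int(subj.site_index)]
                row.update(
                    site=subj.site,
                    ga_weeks=subj.ga_weeks,
                    ga_delivery_weeks=subj.ga_delivery_weeks,
                    delivery_group=subj.delivery_group,
                )
                sample_id = str(subj.subject_id)
                subject_id = str(subj.subject_id)
            elif kind == "qc_pool":
                qc_counter += 1
                inj_id = f"{id_prefix}QC{qc_counter:03d}"
                values = pool * tech_noise()
                sample_id = subject_id = "qc_pool"
            elif kind == "blank":
                blank_counter += 1
                inj_id = f"{id_prefix}BLK{blank_counter:03d}"
                values = blank * tech_noise()
                sample_id = subject_id = "blank"
            else:  # qc_dilution
                level = float(info)
                inj_id = f"{id_prefix}DIL{level:g}"
                values = pool * level * tech_noise()
                # non-linear features saturate: response flat above the lowest level
                values[nonlinear_idx] = pool[nonlinear_idx] * tech_noise()[nonlinear_idx]
                row["dilution_level"] = level
                sample_id = subject_id = "qc_dilution"
            row.update(injection_id=inj_id, sample_id=sample_id, subject_id=subject_id,
                       replicate_group=sample_id)
            rows.append(row)
            columns.append(values * g)

    meta = pd.DataFrame(rows)[META_COLUMNS]
    table = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(feature_ids, name="feature_id"),
        columns=meta["injection_id"].to_list(),
    )

    # left-censor at a low quantile of the study-injection distribution
    study_mask = (meta["type"] == "study").to_numpy()
    threshold = np.quantile(table.loc[:, study_mask].to_numpy().ravel(), cfg.missing_quantile)
    table = table.mask(table < threshold)
    return table, meta, drift_curves


def _make_subjects(
    cfg: SimConfig, rng: np.random.Generator, n: int, prefix: str, all_term: bool
) -> pd.DataFrame:
    lo, hi = cfg.ga_range_weeks
    ga = rng.uniform(lo, hi, size=n)
    n_preterm = 0 if all_term else int(round(cfg.frac_preterm * n))
    group = np.array(["preterm"] * n_preterm + ["term"] * (n - n_preterm))
    rng.shuffle(group)
    # GA at delivery: term ~ N(39.9, 0.8) clipped >= 37, preterm ~ N(31.7, 2.8) clipped < 37
    delivery = np.where(
        group == "term",
        np.clip(rng.normal(39.9, 0.8, size=n), 37.0, 43.0),
        np.clip(rng.normal(31.7, 2.8, size=n), 22.0, 36.9),
    )
    sites = [f"site_{chr(ord('A') + (i % cfg.n_sites))}" for i in range(n)]
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "ga_weeks": np.round(ga, 2),
            "ga_delivery_weeks": np.round(delivery, 1),
            "delivery_group": group,
            "site": sites,
            "site_index": [i % cfg.n_sites for i in range(n)],
        }
    )


def _subject_log_matrix(
    cfg: SimConfig,
    rng: np.random.Generator,
    subjects: pd.DataFrame,
    baselines: np.ndarray,
    slopes_vec: np.ndarray,
) -> np.ndarray:
    """Per-subject log abundance: baseline + slope*GA + biological noise."""
    n_feat = len(baselines)
    ga = subjects["ga_weeks"].to_numpy()
    log_m = baselines[:, None] + slopes_vec[:, None] * ga[None, :]
    bio_sd = np.full((n_feat, len(ga)), cfg.biological_log_sd)
    lo, hi = cfg.preterm_window_weeks
    inflate = (subjects["delivery_group"].to_numpy() == "preterm") & (ga >= lo) & (ga <= hi)
    bio_sd[np.ix_(slopes_vec != 0, inflate)] *= cfg.preterm_var_multiplier
    log_m += rng.normal(0.0, 1.0, size=log_m.shape) * bio_sd
    return log_m


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the discovery cohort.

    Returns
    -------
    table : DataFrame, features x injections (non-negative, NaN = missing)
    meta : DataFrame with one row per injection (``META_COLUMNS``)
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feature_ids = _feature_ids(config.n_features)
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_features)

    special = rng.choice(
        config.n_features,
        size=config.n_informative + config.n_contaminants + config.n_dilution_nonlinear,
        replace=False,
    )
    informative_idx = special[: config.n_informative]
    contaminant_idx = special[config.n_informative : config.n_informative + config.n_contaminants]
    nonlinear_idx = special[config.n_informative + config.n_contaminants :]

    # half-up rounding: 55% of 30 -> 17 positive
    n_pos = int(np.floor(config.frac_positive_slope * config.n_informative + 0.5))
    signs = np.array([1.0] * n_pos + [-1.0] * (config.n_informative - n_pos))
    magnitudes = rng.uniform(*config.slope_range, size=config.n_informative)
    slopes_vec = np.zeros(config.n_features)
    slopes_vec[informative_idx] = signs * magnitudes
    # keep informative features well detected despite negative slopes over the GA range
    mid_ga = float(np.mean(config.ga_range_weeks))
    baselines[informative_idx] = (
        rng.normal(config.baseline_log_mean + 1.0, 0.8, size=config.n_informative)
        - slopes_vec[informative_idx] * mid_ga
    )

    subjects = _make_subjects(config, rng, config.n_subjects, "D", all_term=False)
    log_subject = _subject_log_matrix(config, rng, subjects, baselines, slopes_vec)
    dilution = np.exp(rng.normal(0.0, config.dilution_log_sd, size=config.n_subjects))
    site_offsets = np.exp(rng.normal(0.0, config.site_log_sd, size=(config.n_features, config.n_sites)))

    table, meta, drift_curves = _simulate_injections(
        config, rng, subjects, log_subject, baselines, feature_ids, dilution,
        site_offsets, contaminant_idx, nonlinear_idx, config.n_batches,
    )

    fid = np.asarray(feature_ids)
    truth = GroundTruth(
        ga_weeks=dict(zip(subjects["subject_id"], map(float, subjects["ga_weeks"]))),
        delivery_group=dict(zip(subjects["subject_id"], subjects["delivery_group"])),
        informative_feature_ids=[str(f) for f in fid[informative_idx]],
        slopes={str(f): float(s) for f, s in zip(fid[informative_idx], slopes_vec[informative_idx])},
        dilution_factors=dict(zip(subjects["subject_id"], map(float, dilution))),
        drift_curves=drift_curves,
        baselines={str(f): float(b) for f, b in zip(fid, baselines)},
        contaminant_ids=[str(f) for f in fid[contaminant_idx]],
        dilution_nonlinear_ids=[str(f) for f in fid[nonlinear_idx]],
        site_of_subject=dict(zip(subjects["subject_id"], subjects["site"])),
    )
    return table, meta, truth


def generate_validation_cohort(
    config: SimConfig, shared_truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent term-only cohort sharing the discovery generative parameters.

    New subjects (ids ``V...``), a fresh random stream, and a single
    acquisition batch; informative features, slopes and baselines are reused
    from ``shared_truth`` so a model trained on discovery transfers.
    """
    config.validate()
    if config.n_validation <= 0:
        raise ValueError("n_validation must be positive")
    rng = np.random.default_rng([config.seed, 9001])

    feature_ids = list(shared_truth.baselines)
    baselines = np.array([shared_truth.baselines[f] for f in feature_ids])
    slopes_vec = np.array([shared_truth.slopes.get(f, 0.0) for f in feature_ids])
    contaminant_idx = np.array(
        [feature_ids.index(f) for f in shared_truth.contaminant_ids], dtype=int
    )
    nonlinear_idx = np.array(
        [feature_ids.index(f) for f in shared_truth.dilution_nonlinear_ids], dtype=int
    )

    subjects = _make_subjects(config, rng, config.n_validation, "V", all_term=True)
    log_subject = _subject_log_matrix(config, rng, subjects, baselines, slopes_vec)
    dilution = np.exp(rng.normal(0.0, config.dilution_log_sd, size=config.n_validation))
    site_offsets = np.exp(
        rng.normal(0.0, config.site_log_sd, size=(len(feature_ids), config.n_sites))
    )
    table, meta, _ = _simulate_injections(
        config, rng, subjects, log_subject, baselines, feature_ids, dilution,
        site_offsets, contaminant_idx, nonlinear_idx, n_batches=1, id_prefix="V",
    )
    return table, meta


def generate_correlated_blocks(
    n_samples: int,
    block_sizes: tuple[int, ...] = (10, 10),
    loading: float = 0.9,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x features matrix with planted correlated feature blocks.

    Each block shares one latent factor (features = loading * factor +
    noise), so within-block pairwise correlation is high and between-block
    correlation is zero in expectation — the structure of co-regulated
    metabolite families (e.g. a steroid cluster and an amino-acid cluster).
    Returns the matrix and the per-feature block label.
    """
    rng = np.random.default_rng(seed)
    cols, labels, parts = [], [], []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(0.0, 1.0, size=n_samples)
        block = loading * factor[:, None] + rng.normal(0.0, noise_sd, size=(n_samples, size))
        parts.append(block)
        cols += [f"block{b}_f{j}" for j in range(size)]
        labels += [f"block{b}"] * size
    X = pd.DataFrame(np.hstack(parts), columns=cols)
    return X, pd.Series(labels, index=cols, name="block")


def write_cohort(
    out_dir: str | Path,
    table: pd.DataFrame,
    meta: pd.DataFrame,
    truth: GroundTruth | None = None,
    prefix: str = "cohort",
) -> dict[str, str]:
    """Write table (TSV, features x injections), metadata (CSV) and truth (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": str(out / f"{prefix}_table.tsv"),
        "meta": str(out / f"{prefix}_meta.csv"),
    }
    table.to_csv(paths["table"], sep="\t")
    meta.to_csv(paths["meta"], index=False)
    if truth is not None:
        paths["truth"] = str(out / f"{prefix}_truth.json")
        truth.to_json(paths["truth"])
    return paths
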