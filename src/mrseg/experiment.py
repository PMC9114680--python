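"""Cohort experiments: algorithm comparison and feature-set comparison.

Two simulation experiments mirror the study design:

1. **Algorithm comparison** — LDA, QDA, SVM and ADA are each run under
   patient-level leave-one-out CV with T2w features only.  A Friedman
   test for repeated measurements probes for any difference; if it is
   significant at alpha, all pairwise two-sided Wilcoxon signed-rank
   tests follow with Bonferroni correction over the C(k, 2) pairs.

2. **Feature-set comparison** — a single classifier (ADA by default) is
   run for every requested combination of the four sequence feature
   sets; each non-reference combination is compared with the T2w-only
   reference by a two-sided Wilcoxon signed-rank test, Bonferroni
   corrected over the number of comparisons.

Per-patient results are summarized as median (MED) and interquartile
range (IQR).  Everything is driven by an ``ExperimentConfig`` and a
master seed; a run manifest records the configuration so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import classify as cl
from . import features as ft
from . import phantom as ph
from . import preprocess as pre

ALPHA = 0.05


def summarize(values: "list[float]") -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation quantiles)."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value (exact for n <= 25, ties
    permitting); identical samples give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diff = x - y
    if np.allclose(diff, 0.0):
        return 1.0
    method = "exact" if (diff.size <= 25 and not _has_exact_blockers(diff)) else "approx"
    res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _has_exact_blockers(diff: np.ndarray) -> bool:
    nz = diff[diff != 0]
    return nz.size == 0 or np.unique(np.abs(nz)).size != nz.size


def bonferroni(p: float, n_comparisons: int) -> float:
    return float(min(1.0, p * n_comparisons))


@dataclass
class ComparisonTable:
    """Cohort summaries plus the omnibus and pairwise test results."""

    rows: pd.DataFrame  # per (algorithm|features): MED/IQR of DICE and MSD
    pairwise: pd.DataFrame  # comparison, p_raw, p_adjusted, significant
    friedman_p_dice: float | None
    friedman_p_msd: float | None
    reference: str | None
    per_patient: pd.DataFrame  # long table of MetricsRecords

    def to_csv(self, outdir: Path, prefix: str) -> "list[Path]":
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (
            ("summary", self.rows),
            ("pairwise", self.pairwise),
            ("per_patient", self.per_patient),
        ):
            p = outdir / f"{prefix}_{name}.csv"
            frame.to_csv(p, index=False, float_format="%.12g")
            paths.append(p)
        return paths


# ---------------------------------------------------------------------
# configuration and cohort construction
# ---------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce an experiment run.

    ``phantom_base`` selects the phantom template ("default" for the
    clinical-protocol grids, "small" for the desk-scale grids) and
    ``phantom_overrides`` patches scalar fields of the template (tissue
    parameters, noise, observer amplitude, ...).  Per-patient variation
    jitters the tumor center and semi-axes inside the stated ranges.
    """

    n_patients: int = 8
    phantom_base: str = "small"
    phantom_overrides: dict = field(default_factory=dict)
    center_jitter_mm: float = 1.5
    semiaxis_jitter_frac: float = 0.15
    master_seed: int = 0
    classifiers: tuple = ("LDA", "QDA", "SVM", "ADA")
    best_classifier: str = "ADA"
    hyperparams: dict = field(default_factory=dict)  # per classifier name
    descriptors: tuple | None = None  # None -> all 15 combinations
    margin_mm: float = 20.0
    register: bool = False
    median_radius: int = 1
    h_mm: float = 1.0
    snap_mm: float = 1.0
    alpha: float = ALPHA

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("cohort size must be >= 2")
        if self.descriptors is not None:
            descs = [tuple(d) for d in self.descriptors]
            if len(set(descs)) != len(descs):
                raise ValueError("descriptors must be unique")
            self.descriptors = tuple(descs)
        self.classifiers = tuple(self.classifiers)

    def resolved_descriptors(self) -> "list[ft.FeatureSetDescriptor]":
        if self.descriptors is None:
            return ft.FeatureSetDescriptor.all_combinations()
        return [ft.FeatureSetDescriptor(tuple(d)) for d in self.descriptors]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifiers"] = list(self.classifiers)
        d["descriptors"] = (
            None if self.descriptors is None else [list(x) for x in self.descriptors]
        )
        # JSON-normalize (tuples -> lists) so the dict round-trips exactly
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("descriptors") is not None:
            d["descriptors"] = tuple(tuple(x) for x in d["descriptors"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _coerce_override(key: str, value, current):
    """Rebuild typed phantom fields from plain (JSON-compatible) values."""
    def as_grid(v):
        if isinstance(v, ph.GridSpec):
            return v
        return ph.GridSpec(tuple(v["shape"]), tuple(v["spacing"]))

    def as_rigid(v):
        if isinstance(v, ph.RigidParams):
            return v
        return ph.RigidParams(
            tuple(v.get("rotation_deg", (0, 0, 0))),
            tuple(v.get("translation_mm", (0, 0, 0))),
        )

    if key in ("tumor", "normal"):
        if isinstance(value, ph.TissueParams):
            return value
        return ph.TissueParams(**{**asdict(current), **value})
    if key == "grids":
        return {**current, **{k: as_grid(v) for k, v in value.items()}}
    if key == "misalignment":
        return {**current, **{k: as_rigid(v) for k, v in value.items()}}
    if isinstance(current, dict) and isinstance(value, dict):
        return {**current, **value}
    if isinstance(current, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _base_spec(config: ExperimentConfig) -> ph.PhantomSpec:
    if config.phantom_base == "default":
        spec = ph.PhantomSpec()
    elif config.phantom_base == "small":
        spec = ph.PhantomSpec.small()
    else:
        raise ValueError(f"unknown phantom base {config.phantom_base!r}")
    for key, value in config.phantom_overrides.items():
        if not hasattr(spec, key):
            raise ValueError(f"unknown phantom field {key!r}")
        setattr(spec, key, _coerce_override(key, value, getattr(spec, key)))
    return spec


def build_cohort(config: ExperimentConfig) -> "list[ph.MultiSequenceStudy]":
    """Generate the phantom cohort with per-patient geometric variation."""
    base = _base_spec(config)
    cohort = []
    for i in range(config.n_patients):
        ss = np.random.SeedSequence([config.master_seed, 0xC0F0, i])
        rng = np.random.default_rng(ss)
        center = np.asarray(base.resolved_tumor_center())
        center = center + rng.uniform(
            -config.center_jitter_mm, config.center_jitter_mm, size=3
        )
        axes = np.asarray(base.tumor_semiaxes_mm) * rng.uniform(
            1 - config.semiaxis_jitter_frac, 1 + config.semiaxis_jitter_frac, size=3
        )
        spec = _base_spec(config)
        spec.tumor_center_mm = tuple(center)
        spec.tumor_semiaxes_mm = tuple(axes)
        study_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        cohort.append(ph.generate_study(spec, seed=study_seed))
    return cohort


def _prepare_cohort(config: ExperimentConfig, cohort=None):
    if cohort is None:
        cohort = build_cohort(config)
    out = []
    for s in cohort:
        if not s.is_preprocessed:
            s = pre.preprocess_study(
                s, margin_mm=config.margin_mm, estimate_transforms=config.register
            )
        out.append(s)
    return out


# ---------------------------------------------------------------------
# the two experiments
# ---------------------------------------------------------------------

def _records_frame(results: "list[cl.SegmentationResults]") -> pd.DataFrame:
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    return frame.sort_values(
        ["algorithm", "features", "patient_id"], ignore_index=True
    )


def _summary_rows(results, key):
    rows = []
    for label, res in results.items():
        med_d, iqr_d = summarize(res.dice.tolist())
        msd_vals = res.msd[~np.isnan(res.msd)]
        med_m, iqr_m = summarize(msd_vals.tolist()) if msd_vals.size else (np.nan, np.nan)
        rows.append(
            {
                key: label,
                "dice_med": med_d, "dice_iqr": iqr_d,
                "msd_med": med_m, "msd_iqr": iqr_m,
                "n_patients": len(res.records),
                "n_empty": int(sum(r.empty_prediction for r in res.records)),
            }
        )
    return pd.DataFrame(rows)


def compare_algorithms_table(
    dice_by_algorithm: "dict[str, np.ndarray]", alpha: float = ALPHA
) -> tuple[float, pd.DataFrame]:
    """Friedman omnibus plus Bonferroni-corrected pairwise Wilcoxon tests.

    Post-hoc pairwise tests are run only when the Friedman test is
    significant at ``alpha``; the Bonferroni family is all C(k, 2) pairs.
    """
    names = list(dice_by_algorithm)
    vectors = [np.asarray(dice_by_algorithm[n], dtype=float) for n in names]
    if all(np.array_equal(v, vectors[0]) for v in vectors[1:]):
        friedman_p = 1.0  # no-effect null: identical per-patient vectors
    elif len(vectors) == 2:
        friedman_p = wilcoxon_signed_rank(vectors[0], vectors[1])
    else:
        friedman_p = float(stats.friedmanchisquare(*vectors).pvalue)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    if friedman_p < alpha:
        n_comp = len(pairs)
        for a, b in pairs:
            p = wilcoxon_signed_rank(dice_by_algorithm[a], dice_by_algorithm[b])
            p_adj = bonferroni(p, n_comp)
            rows.append(
                {
                    "comparison": f"{a} vs {b}", "p_raw": p,
                    "p_adjusted": p_adj, "significant": p_adj < alpha,
                }
            )
    pairwise = pd.DataFrame(
        rows, columns=["comparison", "p_raw", "p_adjusted", "significant"]
    )
    return friedman_p, pairwise


def run_algorithm_comparison(
    config: ExperimentConfig, cohort=None
) -> ComparisonTable:
    """LOO-CV of every classifier on T2w features, with statistics."""
    cohort = _prepare_cohort(config, cohort)
    desc = ft.FeatureSetDescriptor.of(ph.T2W)
    matrices = {s.patient_id: ft.patient_matrix(s, desc) for s in cohort}
    results = {}
    for kind in config.classifiers:
        model = cl.SegmentationModel(
            cohort,
            classifier=cl.ClassifierKind(kind, config.hyperparams.get(kind, {})),
            feature_set=desc,
            margin_mm=config.margin_mm, register=config.register,
            median_radius=config.median_radius, h_mm=config.h_mm,
            snap_mm=config.snap_mm,
        )
        results[kind] = model.fit(seed=config.master_seed, matrices=matrices)
    dice_by_alg = {k: r.dice for k, r in results.items()}
    friedman_dice, pairwise = compare_algorithms_table(dice_by_alg, config.alpha)
    msd_by_alg = {
        k: np.nan_to_num(r.msd, nan=np.nanmax(r.msd) if np.isfinite(r.msd).any() else 0.0)
        for k, r in results.items()
    }
    friedman_msd, _ = compare_algorithms_table(msd_by_alg, config.alpha)
    return ComparisonTable(
        rows=_summary_rows(results, "algorithm"),
        pairwise=pairwise,
        friedman_p_dice=friedman_dice,
        friedman_p_msd=friedman_msd,
        reference=None,
        per_patient=_records_frame(list(results.values())),
    )


def run_featureset_comparison(
    config: ExperimentConfig, cohort=None
) -> ComparisonTable:
    """LOO-CV of one classifier per feature-set combination, each compared
    with the T2w-only reference by Bonferroni-corrected Wilcoxon tests."""
    cohort = _prepare_cohort(config, cohort)
    descriptors = config.resolved_descriptors()
    ref_desc = ft.FeatureSetDescriptor.of(ph.T2W)
    if ref_desc not in descriptors:
        descriptors = [ref_desc] + descriptors
    full = ft.FeatureSetDescriptor(tuple(ft.SEQUENCE_ORDER))
    full_matrices = {s.patient_id: ft.patient_matrix(s, full) for s in cohort}

    def sliced(desc: ft.FeatureSetDescriptor):
        cols = [
            i for i, name in enumerate(full_matrices[cohort[0].patient_id].feature_names)
            if name.split("_")[0] in desc.members
        ]
        out = {}
        for pid, m in full_matrices.items():
            out[pid] = ft.FeatureMatrix(
                values=m.values[:, cols],
                voxel_indices=m.voxel_indices,
                labels=m.labels,
                patient_id=pid,
                descriptor=desc,
                feature_names=tuple(m.feature_names[i] for i in cols),
                norm_stats=None,
            )
        return out

    best = cl.ClassifierKind(
        config.best_classifier, config.hyperparams.get(config.best_classifier, {})
    )
    results = {}
    for desc in descriptors:
        model = cl.SegmentationModel(
            cohort, classifier=best, feature_set=desc,
            margin_mm=config.margin_mm, register=config.register,
            median_radius=config.median_radius, h_mm=config.h_mm,
            snap_mm=config.snap_mm,
        )
        results[str(desc)] = model.fit(
            seed=config.master_seed, matrices=sliced(desc)
        )

    ref = str(ref_desc)
    others = [d for d in results if d != ref]
    n_comp = len(others)
    rows = []
    for d in others:
        p = wilcoxon_signed_rank(results[d].dice, results[ref].dice)
        p_adj = bonferroni(p, n_comp)
        rows.append(
            {
                "comparison": f"{d} vs {ref}", "p_raw": p,
                "p_adjusted": p_adj, "significant": p_adj < config.alpha,
            }
        )
    pairwise = pd.DataFrame(
        rows, columns=["comparison", "p_raw", "p_adjusted", "significant"]
    )
    return ComparisonTable(
        rows=_summary_rows(results, "features"),
        pairwise=pairwise,
        friedman_p_dice=None,
        friedman_p_msd=None,
        reference=ref,
        per_patient=_records_frame(list(results.values())),
    )


# ---------------------------------------------------------------------
# reporting and reproducibility
# ---------------------------------------------------------------------

def write_report(
    tables: "dict[str, ComparisonTable]",
    config: ExperimentConfig,
    outdir,
) -> dict:
    """Write per-patient CSVs, comparison CSVs and a run manifest.

    Returns the manifest dict; the manifest records the full config, the
    master seed and software versions, and is sufficient for
    ``rerun_from_manifest`` to reproduce every CSV bit-for-bit.
    """
    import sklearn
    import scipy
    import skimage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    stats_block = {}
    for name, table in tables.items():
        files += [str(p.name) for p in table.to_csv(outdir, name)]
        stats_block[name] = {
            "friedman_p_dice": table.friedman_p_dice,
            "friedman_p_msd": table.friedman_p_msd,
            "reference": table.reference,
        }
    from . import __version__
    from .classify import _stable_patient_seed

    patient_ids = sorted(
        set().union(*(set(t.per_patient["patient_id"]) for t in tables.values()))
    )
    fold_seeds = {
        pid: _stable_patient_seed(config.master_seed, pid, salt=2)
        for pid in patient_ids
    }
    manifest = {
        "fold_seeds": fold_seeds,
        "experiments": sorted(tables),
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "files": files,
        "statistics": stats_block,
        "versions": {
            "mrseg": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


EXPERIMENT_RUNNERS = {
    "algorithms": run_algorithm_comparison,
    "featuresets": run_featureset_comparison,
}


def run_experiments(
    config: ExperimentConfig, which=("algorithms", "featuresets"), outdir=None
) -> "dict[str, ComparisonTable]":
    """Run the requested experiments on one shared cohort; optionally report."""
    cohort = _prepare_cohort(config)
    tables = {name: EXPERIMENT_RUNNERS[name](config, cohort=cohort) for name in which}
    if outdir is not None:
        write_report(tables, config, outdir)
    return tables


def rerun_from_manifest(manifest_path, outdir) -> dict:
    """Re-run the experiments recorded in a manifest into ``outdir``."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = ExperimentConfig.from_dict(manifest["config"])
    run_experiments(config, which=tuple(manifest["experiments"]), outdir=outdir)
    with open(Path(outdir) / "manifest.json") as fh:
        return json.load(fh)
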