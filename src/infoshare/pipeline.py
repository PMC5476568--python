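"""End-to-end study pipeline: simulate/load → wSMI → statistics → SVM.

A single :class:`PipelineConfig` drives the full analysis sequence:

1. simulate (or load) a two-group cohort;
2. per-subject wSMI connectivity matrices;
3. ROI-pair comparison (rank-sum + FDR + Cohen's d over the 21 pairs);
4. distance analysis of the two frontal seed ROIs (tertile bins, label-
   permutation tests);
5. stage-1 seed analysis of the frontal ROIs, stage-2 seed analysis from
   the five highest-scoring external electrodes of each significant region;
6. construction of the six connectivity variables (CNVs) from the distance
   and seed results, and NPV / CNV / BOTH repeated-holdout SVM
   classification with ROC/AUC.

Low-density replication is the same pipeline with the 20-channel
``standard1020`` layout in the design.

Randomness: the master seed fans out by fixed offsets — ``seed`` drives the
cohort, ``seed + 1`` the permutation tests, ``seed + 2`` the classifier
holdouts — so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassificationReport,
    FeatureSpec,
    build_features,
    roc_auc,
    svm_repeated_holdout,
)
from .montage import Montage, build_montage, distance_matrix, tertile_bins
from .simulate import Cohort, CohortDesign, EpochedEEG, simulate_cohort
from .stats import (
    ALPHA,
    SeedMap,
    permutation_profile_test,
    roi_pair_comparison,
    second_stage_seeds,
    seed_analysis,
)
from .topo import distance_profile, roi_pair_means
from .wsmi import SymbolParams, connectivity_matrix

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "compute_connectivity",
    "default_cnv_spec",
    "save_cohort",
    "load_cohort",
]

#: Distance ranges of the two distance-based connectivity variables
#: (seed ROI, d_min, d_max), as selected in the emulated study.
LEFT_FRONTAL_RANGE = ("R1", 0.0, 1.45)
RIGHT_FRONTAL_RANGE = ("R2", 0.6, 1.45)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one full pipeline run."""

    design: CohortDesign = field(default_factory=CohortDesign)
    k: int = 3
    tau_ms: float = 16.0
    fdr_q: float = ALPHA
    n_perm: int = 5000
    n_train_per_group: int = 7
    n_repeats: int = 1000
    svm_C: float = 1.0
    seed: int = 0
    out_dir: str | None = None

    def symbol_params(self) -> SymbolParams:
        return SymbolParams(k=self.k, tau_ms=self.tau_ms, fs=self.design.fs)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        design_raw = raw.pop("design", {})
        allowed = {f.name for f in dataclasses.fields(cls)} - {"design"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d_allowed = {f.name for f in dataclasses.fields(CohortDesign)}
        d_unknown = set(design_raw) - d_allowed
        if d_unknown:
            raise ValueError(f"unknown design keys: {sorted(d_unknown)}")
        if "altered_links" in design_raw:
            design_raw["altered_links"] = tuple(
                tuple(link) for link in design_raw["altered_links"]
            )
        if "band" in design_raw:
            design_raw["band"] = tuple(design_raw["band"])
        return cls(design=CohortDesign(**design_raw), **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    cohort: Cohort
    roi_pair_table: pd.DataFrame
    roi_pair_vectors: pd.DataFrame
    distance: dict[str, dict]  # roi -> {"bins", "profiles", "test"}
    seed_stage1: dict[str, SeedMap]
    stage2_seeds: dict[str, tuple[str, ...]]
    seed_stage2: dict[str, SeedMap]
    derived_rois: dict[str, tuple[str, ...]]
    cnv_fallbacks: tuple[str, ...]
    feature_spec: FeatureSpec
    features: dict[str, pd.DataFrame]
    reports: dict[str, ClassificationReport]
    aucs: dict[str, float]


def compute_connectivity(
    cohort: Cohort, params: SymbolParams | None = None
) -> dict[str, np.ndarray]:
    """wSMI connectivity matrix per subject (cached on the cohort)."""
    if cohort.connectivity is None:
        params = params or SymbolParams()
        cohort.connectivity = {
            sid: connectivity_matrix(eeg.data, params)
            for sid, eeg in cohort.eeg.items()
        }
    return cohort.connectivity


def default_cnv_spec(
    montage: Montage,
    stage2_seeds: dict[str, tuple[str, ...]],
    derived_rois: dict[str, tuple[str, ...]],
    npv_columns: tuple[str, ...] = (),
) -> tuple[FeatureSpec, tuple[str, ...]]:
    """Six connectivity variables from the seed/distance results.

    Electrode sets that the seed stages failed to populate (possible on
    null cohorts, where nothing is significant) fall back to the full
    scalp ROI so that the features stay computable; the returned tuple of
    names records which sets fell back.
    """
    fallbacks = []

    def pick(result: dict, key: str, default_roi: str, name: str):
        chans = result.get(key, ())
        if chans:
            return tuple(chans)
        fallbacks.append(name)
        return tuple(montage.roi_channels(default_roi))

    lp_hubs = pick(stage2_seeds, "R5", "R5", "left_parietal_hubs")
    rt_hubs = pick(stage2_seeds, "R3", "R3", "right_temporal_hubs")
    new_lf = pick(derived_rois, "R1", "R1", "new_left_frontal")
    new_rf = pick(derived_rois, "R2", "R2", "new_right_frontal")
    spec = FeatureSpec(
        range_features=(
            ("cnv_lf_distance",) + LEFT_FRONTAL_RANGE,
            ("cnv_rf_distance",) + RIGHT_FRONTAL_RANGE,
        ),
        set_features=(
            ("cnv_rf_rt", new_rf, rt_hubs),
            ("cnv_rf_lp", new_rf, lp_hubs),
            ("cnv_lf_rt", new_lf, rt_hubs),
            ("cnv_lf_lp", new_lf, lp_hubs),
        ),
        npv_columns=npv_columns,
    )
    return spec, tuple(fallbacks)


def _distance_stage(
    cohort: Cohort, conn: dict[str, np.ndarray], config: PipelineConfig
) -> dict[str, dict]:
    m = cohort.montage
    bins = tertile_bins(float(distance_matrix(m).max()))
    out: dict[str, dict] = {}
    groups = cohort.groups
    for roi in ("R1", "R2"):
        profiles = pd.DataFrame(
            {
                sid: distance_profile(conn[sid], m, roi, bins).means
                for sid in cohort.subject_ids
            }
        ).T
        pat = profiles.loc[groups == "patient"].to_numpy()
        ctl = profiles.loc[groups == "control"].to_numpy()
        keep = ~np.isnan(pat).any(axis=0) & ~np.isnan(ctl).any(axis=0)
        test = permutation_profile_test(
            pat[:, keep], ctl[:, keep],
            n_perm=config.n_perm, seed=config.seed + 1,
        )
        test.index = np.flatnonzero(keep)
        out[roi] = {"bins": bins, "profiles": profiles, "test": test,
                    "bins_tested": np.flatnonzero(keep)}
    return out


def _seed_stages(
    cohort: Cohort, conn: dict[str, np.ndarray], config: PipelineConfig
) -> tuple[dict, dict, dict, dict]:
    m = cohort.montage
    mats = np.stack([conn[sid] for sid in cohort.subject_ids])
    groups = cohort.groups.to_numpy()
    stage1 = {
        roi: seed_analysis(mats, groups, m, roi, q=config.fdr_q)
        for roi in ("R1", "R2")
    }
    stage2_seed_sets = second_stage_seeds(stage1["R1"], stage1["R2"], m)
    stage2 = {
        roi: seed_analysis(mats, groups, m, list(chans), q=config.fdr_q)
        for roi, chans in stage2_seed_sets.items()
    }
    derived: dict[str, tuple[str, ...]] = {}
    for roi, smap in stage2.items():
        per = smap.per_electrode
        hot = per.index[per["signed_score"] > -np.log10(ALPHA)]
        for frontal in ("R1", "R2"):
            hits = tuple(e for e in hot if m.roi_of[e] == frontal)
            if hits:
                derived[frontal] = tuple(
                    sorted(set(derived.get(frontal, ())) | set(hits))
                )
    return stage1, stage2_seed_sets, stage2, derived


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Execute the full analysis and optionally write a result bundle."""
    cohort = cohort or simulate_cohort(config.design)
    conn = compute_connectivity(cohort, config.symbol_params())
    groups = cohort.groups

    vectors = pd.DataFrame(
        {sid: roi_pair_means(conn[sid], cohort.montage)
         for sid in cohort.subject_ids}
    ).T
    roi_table = roi_pair_comparison(vectors, groups, q=config.fdr_q)

    distance = _distance_stage(cohort, conn, config)
    stage1, stage2_seed_sets, stage2, derived = _seed_stages(
        cohort, conn, config
    )

    spec, fallbacks = default_cnv_spec(
        cohort.montage, stage2_seed_sets, derived,
        npv_columns=tuple(cohort.npv.columns),
    )
    features: dict[str, pd.DataFrame] = {}
    reports: dict[str, ClassificationReport] = {}
    aucs: dict[str, float] = {}
    labels = [groups[sid] for sid in cohort.npv.index]
    for mode in ("NPV", "CNV", "BOTH"):
        feats = build_features(cohort.npv, conn, cohort.montage, spec, mode)
        features[mode] = feats
        reports[mode] = svm_repeated_holdout(
            feats, labels,
            n_train_per_group=config.n_train_per_group,
            n_repeats=config.n_repeats,
            seed=config.seed + 2,
            C=config.svm_C,
        )
        aucs[mode] = roc_auc(reports[mode])[1]

    result = PipelineResult(
        config=config, cohort=cohort,
        roi_pair_table=roi_table, roi_pair_vectors=vectors,
        distance=distance,
        seed_stage1=stage1, stage2_seeds=stage2_seed_sets,
        seed_stage2=stage2, derived_rois=derived,
        cnv_fallbacks=fallbacks,
        feature_spec=spec, features=features,
        reports=reports, aucs=aucs,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


# ---------------------------------------------------------------------------
# serialization


def _write_bundle(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    m = cohort.montage
    pd.DataFrame(
        {
            "label": m.labels,
            "x": m.positions[:, 0],
            "y": m.positions[:, 1],
            "z": m.positions[:, 2],
            "roi": [m.roi_of[lb] for lb in m.labels],
        }
    ).to_csv(out / "montage.csv", index=False)
    cohort.groups.rename_axis("subject").to_csv(out / "cohort.csv")
    cohort.npv.rename_axis("subject").to_csv(out / "npv.csv")
    result.roi_pair_table.to_csv(out / "roi_pairs.csv")
    for roi, d in result.distance.items():
        d["profiles"].rename_axis("subject").to_csv(
            out / f"distance_profiles_{roi}.csv"
        )
        d["test"].rename_axis("bin").to_csv(out / f"distance_test_{roi}.csv")
    for roi, smap in result.seed_stage1.items():
        smap.per_electrode.to_csv(out / f"seed_stage1_{roi}.csv")
    for roi, smap in result.seed_stage2.items():
        smap.per_electrode.to_csv(out / f"seed_stage2_{roi}.csv")
    for mode, feats in result.features.items():
        feats.rename_axis("subject").to_csv(
            out / f"features_{mode.lower()}.csv"
        )
    for mode, rep in result.reports.items():
        rep.per_repeat.to_csv(out / f"repeats_{mode.lower()}.csv", index=False)
        curve, auc = roc_auc(rep)
        curve.to_csv(out / f"roc_{mode.lower()}.csv", index=False)
    summary = {
        "version": __version__,
        "seed": result.config.seed,
        "config": _config_echo(result.config),
        "cnv_fallbacks": list(result.cnv_fallbacks),
        "stage2_seeds": {k: list(v) for k, v in result.stage2_seeds.items()},
        "derived_rois": {k: list(v) for k, v in result.derived_rois.items()},
        "classification": {
            mode: dict(rep.summary, auc=result.aucs[mode],
                       classification_rate=rep.classification_rate)
            for mode, rep in result.reports.items()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def _config_echo(config: PipelineConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["design"]["npv_spec"] = {
        name: dataclasses.asdict(v)
        for name, v in config.design.npv_spec.items()
    }
    return raw


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as plain-text files (one EEG table per subject)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.groups.rename_axis("subject").to_csv(out / "cohort.csv")
    cohort.npv.rename_axis("subject").to_csv(out / "npv.csv")
    m = cohort.montage
    pd.DataFrame(
        {"label": m.labels, "x": m.positions[:, 0], "y": m.positions[:, 1],
         "z": m.positions[:, 2], "roi": [m.roi_of[lb] for lb in m.labels]}
    ).to_csv(out / "montage.csv", index=False)
    for sid, eeg in cohort.eeg.items():
        ch, ep, ns = eeg.data.shape
        header = f"channels={ch} epochs={ep} samples={ns} fs={eeg.fs}"
        np.savetxt(out / f"eeg_{sid}.txt", eeg.data.reshape(ch * ep, ns),
                   fmt="%.10e", header=header)


def load_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort written by :func:`save_cohort`, validating layout."""
    src = Path(in_dir)
    errors = []
    for required in ("cohort.csv", "npv.csv", "montage.csv"):
        if not (src / required).exists():
            errors.append(f"missing {required}")
    if errors:
        raise FileNotFoundError("; ".join(errors))
    groups = pd.read_csv(src / "cohort.csv", index_col="subject")["group"]
    npv = pd.read_csv(src / "npv.csv", index_col="subject")
    mdf = pd.read_csv(src / "montage.csv")
    montage = Montage(
        labels=tuple(mdf["label"]),
        positions=mdf[["x", "y", "z"]].to_numpy(),
        roi_of=dict(zip(mdf["label"], mdf["roi"])),
    )
    eeg: dict[str, EpochedEEG] = {}
    for sid in groups.index:
        path = src / f"eeg_{sid}.txt"
        if not path.exists():
            errors.append(f"subject {sid} has no EEG file {path.name}")
            continue
        with open(path) as fh:
            meta = dict(
                kv.split("=") for kv in fh.readline().lstrip("# ").split()
            )
        flat = np.loadtxt(path)
        shape = (int(meta["channels"]), int(meta["epochs"]),
                 int(meta["samples"]))
        eeg[sid] = EpochedEEG(
            subject_id=sid, data=flat.reshape(shape), fs=float(meta["fs"])
        )
    if errors:
        raise FileNotFoundError("; ".join(errors))
    subjects = [(sid, groups[sid]) for sid in groups.index]
    return Cohort(subjects=subjects, eeg=eeg, npv=npv, montage=montage)
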