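"""End-to-end study orchestration.

Runs the two study arms — M1 (features from raw ROIs) and M2 (features
from unsharp-enhanced ROIs) — over a labeled ROI set, producing:

* a per-ROI feature table (10 features) for each arm,
* the 2 x 10 p-value table from the per-feature t-test screen,
* per-feature K-NN and SVM evaluation reports,
* the four feature-combination K-NN reports
  (first-order+GLCM, first-order+GLCM+FD, first-order+FD, GLCM+FD),
* a run log with seed, parameters and a config hash.

Enhancement in the M2 arm is applied per ROI, before all feature
computation.  Degenerate per-ROI features (undefined skewness/kurtosis/
correlation on constant ROIs, fractal dimension of an empty edge map) are
recorded as missing and excluded listwise only from the affected model.
"""

from __future__ import annotations

import hashlib
import json
import os
import platform
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import KnnConfig, SplitPlan, cross_validate, svm_evaluate
from .enhance import EnhanceParams, unsharp_enhance
from .errors import DegenerateInputError, InvalidArgumentError
from .phantom import LabeledRoiSet, PhantomConfig, generate_roi_set
from .fractal import fd_pair
from .roi_io import load_grayscale, read_manifest
from .stats import pvalue_table, screen_features
from .texture import angle_averaged_features, first_order_features, histogram

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "FEATURE_COMBINATIONS",
    "RunConfig",
    "extract_roi_features",
    "extract_all_features",
    "load_roi_set",
    "run_study",
]

FEATURE_NAMES = ["SD", "SK", "KR", "C", "H", "CR", "E", "EN", "FD_I", "FD_II"]

FEATURE_GROUPS = {
    "first_order": ["SD", "SK", "KR"],
    "glcm": ["C", "H", "CR", "E", "EN"],
    "fd": ["FD_I", "FD_II"],
}

FEATURE_COMBINATIONS = {
    "first_order+glcm": FEATURE_GROUPS["first_order"] + FEATURE_GROUPS["glcm"],
    "first_order+glcm+fd": FEATURE_GROUPS["first_order"]
    + FEATURE_GROUPS["glcm"]
    + FEATURE_GROUPS["fd"],
    "first_order+fd": FEATURE_GROUPS["first_order"] + FEATURE_GROUPS["fd"],
    "glcm+fd": FEATURE_GROUPS["glcm"] + FEATURE_GROUPS["fd"],
}


@dataclass
class RunConfig:
    """Configuration of a full study run.

    Exactly one of ``input_dir`` (with ``manifest``) or ``phantom`` must be
    given.
    """

    phantom: PhantomConfig | None = None
    input_dir: str | None = None
    manifest: str | None = None
    method: str = "both"  # M1 | M2 | both
    enhance_params: EnhanceParams = field(default_factory=EnhanceParams)
    glcm_delta: int = 1
    log_sigma: float = 2.0
    split_plan: SplitPlan = field(default_factory=SplitPlan)
    knn_config: KnnConfig = field(default_factory=KnnConfig)
    svm_degree: int = 3
    output_dir: str | None = None
    make_charts: bool = False

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.input_dir is None):
            raise InvalidArgumentError(
                "exactly one of 'phantom' or 'input_dir' must be provided"
            )
        if self.method not in ("M1", "M2", "both"):
            raise InvalidArgumentError("method must be 'M1', 'M2' or 'both'")

    @property
    def methods(self) -> list[str]:
        return ["M1", "M2"] if self.method == "both" else [self.method]

    def config_hash(self) -> str:
        payload = {
            "phantom": asdict(self.phantom) if self.phantom else None,
            "input_dir": self.input_dir,
            "manifest": self.manifest,
            "method": self.method,
            "enhance_params": asdict(self.enhance_params),
            "glcm_delta": self.glcm_delta,
            "log_sigma": self.log_sigma,
            "split_plan": asdict(self.split_plan),
            "knn_config": asdict(self.knn_config),
            "svm_degree": self.svm_degree,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def extract_roi_features(
    image: np.ndarray,
    method: str = "M1",
    enhance_params: EnhanceParams = EnhanceParams(),
    glcm_delta: int = 1,
    log_sigma: float = 2.0,
) -> dict[str, float]:
    """The 10-feature vector of one ROI; degenerate entries come back NaN."""
    if method == "M2":
        image = unsharp_enhance(image, enhance_params)
    elif method != "M1":
        raise InvalidArgumentError("method must be 'M1' or 'M2'")
    out: dict[str, float] = {}

    dist = histogram(image)
    try:
        fo = first_order_features(dist)
        out.update(SD=fo.sd, SK=fo.sk, KR=fo.kr)
    except DegenerateInputError:
        out.update(SD=0.0, SK=np.nan, KR=np.nan)

    g = angle_averaged_features(image, delta=glcm_delta, degenerate_correlation="nan")
    out.update(C=g.c, H=g.h, CR=g.cr, E=g.e, EN=g.en)

    try:
        fd_i, fd_ii = fd_pair(image, log_sigma=log_sigma)
        out.update(FD_I=fd_i.fd, FD_II=fd_ii.fd)
    except DegenerateInputError:
        out.update(FD_I=np.nan, FD_II=np.nan)
    return out


def extract_all_features(
    rois: LabeledRoiSet | Sequence[np.ndarray],
    method: str = "M1",
    cfg: RunConfig | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table over a ROI set: one row per ROI, 10 feature columns."""
    if isinstance(rois, LabeledRoiSet):
        images, labs = rois.rois, rois.labels
    else:
        images, labs = list(rois), list(labels or [])
        if len(images) != len(labs):
            raise InvalidArgumentError("labels must be provided, one per ROI")
    if len(images) == 0:
        raise InvalidArgumentError("empty ROI set")
    enhance_params = cfg.enhance_params if cfg else EnhanceParams()
    glcm_delta = cfg.glcm_delta if cfg else 1
    log_sigma = cfg.log_sigma if cfg else 2.0
    rows = []
    for i, (img, lab) in enumerate(zip(images, labs)):
        feats = extract_roi_features(
            img,
            method=method,
            enhance_params=enhance_params,
            glcm_delta=glcm_delta,
            log_sigma=log_sigma,
        )
        rows.append({"roi_id": i, "label": lab, "method": method, **feats})
    return pd.DataFrame(rows, columns=["roi_id", "label", "method", *FEATURE_NAMES])


def load_roi_set(input_dir: str, manifest: str) -> tuple[list[np.ndarray], list[str]]:
    """Load ROIs named in a manifest CSV (columns: filename, label)."""
    df = read_manifest(manifest)
    images = [load_grayscale(os.path.join(input_dir, f)) for f in df["filename"]]
    return images, df["label"].tolist()


def _evaluate_method(
    table: pd.DataFrame, cfg: RunConfig
) -> dict[str, dict]:
    labels = table["label"].to_numpy()
    feats = table[FEATURE_NAMES]
    single_knn = {
        name: cross_validate(
            feats, labels, cfg.split_plan, cfg.knn_config, feature_subset=[name]
        ).to_dict()
        for name in FEATURE_NAMES
    }
    single_svm = {
        name: svm_evaluate(
            feats,
            labels,
            cfg.split_plan,
            degree=cfg.svm_degree,
            feature_subset=[name],
        ).to_dict()
        for name in FEATURE_NAMES
    }
    combo_knn = {
        combo: cross_validate(
            feats, labels, cfg.split_plan, cfg.knn_config, feature_subset=subset
        ).to_dict()
        for combo, subset in FEATURE_COMBINATIONS.items()
    }
    return {
        "single_feature_knn": single_knn,
        "single_feature_svm": single_svm,
        "combination_knn": combo_knn,
    }


def _bar_chart(path: str, reports: dict[str, dict], title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(reports)
    accs = [reports[n]["test_accuracy"] for n in names]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(names, accs, color="#4878a8")
    ax.set_ylabel("test accuracy (%)")
    ax.set_ylim(0, 100)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(cfg: RunConfig) -> dict:
    """Run the full study and return (and optionally write) the report."""
    if cfg.phantom is not None:
        roi_set = generate_roi_set(cfg.phantom)
        images, labels = roi_set.rois, roi_set.labels
        seed = cfg.phantom.seed
    else:
        images, labels = load_roi_set(cfg.input_dir, cfg.manifest)
        seed = cfg.split_plan.seed

    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "n_rois": len(images),
        "package_version": __version__,
        "python_version": platform.python_version(),
        "methods": {},
    }
    tables: dict[str, pd.DataFrame] = {}
    screens = {}
    for method in cfg.methods:
        table = extract_all_features(images, method=method, cfg=cfg, labels=labels)
        tables[method] = table
        results = screen_features(table, feature_columns=FEATURE_NAMES)
        screens[method] = results
        report["methods"][method] = {
            "p_values": {r.feature_name: r.p_value for r in results},
            "significant_features": [r.feature_name for r in results if r.significant],
            **_evaluate_method(table, cfg),
        }

    if cfg.output_dir is not None:
        os.makedirs(cfg.output_dir, exist_ok=True)
        for method, table in tables.items():
            table.to_csv(
                os.path.join(cfg.output_dir, f"features_{method}.csv"), index=False
            )
        pvalue_table(screens).to_csv(os.path.join(cfg.output_dir, "pvalues.csv"))
        with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if cfg.make_charts:
            for method in cfg.methods:
                for clf in ("knn", "svm"):
                    _bar_chart(
                        os.path.join(cfg.output_dir, f"accuracy_{clf}_{method}.png"),
                        report["methods"][method][f"single_feature_{clf}"],
                        f"Per-feature {clf.upper()} test accuracy ({method})",
                    )
    return report
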