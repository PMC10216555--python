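"""End-to-end orchestration: fit → maps → QC → WMTI → ROI means → stats → report.

A pipeline run is driven by a :class:`PipelineConfig` (constructable from a
YAML file); every run writes a resolved-config copy plus a ``run_info.json``
stamping each artifact set with the config hash and seed, so reruns with an
identical config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .metrics import QC_MK_BOUNDS
from .model import DiffusionKurtosisModel, FitOptions
from .roistats import (DEFAULT_PAIRS, ALPHA_COMPARISONS, ALPHA_CORRELATIONS,
                       N_BOOT_DEFAULT, compare_rois, marker_correlations,
                       report, roc_analysis, roi_means)
from .scheme import read_bval_bvec

logger = logging.getLogger(__name__)


@dataclass
class CaseInputs:
    """Paths of one co-registered case."""

    case_id: str
    dwi: str
    bval: str
    bvec: str
    cbf: str | None = None
    rois: str | None = None


@dataclass
class PipelineConfig:
    cases: list[CaseInputs] = field(default_factory=list)
    table: str | None = None          # pre-built ROI table (skips image stages)
    markers: str | None = None        # optional per-case marker CSV to join
    out_dir: str = "gliodki_out"
    weighting: str = "wls"
    ka_variant: str = "eigen"
    n_sphere: int = 250
    qc_bounds: tuple[float, float] = QC_MK_BOUNDS
    pairs: tuple[tuple[int, int], ...] = DEFAULT_PAIRS
    alpha_comparisons: float = ALPHA_COMPARISONS
    alpha_correlations: float = ALPHA_CORRELATIONS
    n_boot: int = N_BOOT_DEFAULT
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.qc_bounds
        if not lo < hi:
            raise ValueError("QC thresholds must satisfy lower < upper")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cases = [CaseInputs(**c) for c in raw.pop("cases", [])]
        if "qc_bounds" in raw:
            raw["qc_bounds"] = tuple(raw["qc_bounds"])
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        return cls(cases=cases, **raw)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]


def _check_inputs(config: PipelineConfig) -> None:
    missing = []
    for case in config.cases:
        for name in ("dwi", "bval", "bvec", "cbf", "rois"):
            p = getattr(case, name)
            if p is not None and not Path(p).exists():
                missing.append(p)
    for p in (config.table, config.markers):
        if p is not None and not Path(p).exists():
            missing.append(p)
    if missing:
        raise FileNotFoundError(f"missing input: {missing[0]}")


def process_case(case: CaseInputs, config: PipelineConfig, out: Path) -> pd.DataFrame:
    """fit → maps → qc → wmti → roi_means for one case; writes its maps."""
    scheme = read_bval_bvec(case.bval, case.bvec)
    dwi, affine = gio.load_nifti(case.dwi)
    rois, _ = gio.load_nifti(case.rois)
    rois = np.rint(rois).astype(int)
    cbf = gio.load_nifti(case.cbf)[0] if case.cbf else None

    # fit only what the ROI stage reads; background stays unfitted
    model = DiffusionKurtosisModel(dwi, scheme, mask=rois > 0,
                                   options=FitOptions(weighting=config.weighting))
    results = model.fit()
    scalars = results.scalar_maps(n_sphere=config.n_sphere,
                                  ka_variant=config.ka_variant)
    from .metrics import qc_filter
    if tuple(config.qc_bounds) != QC_MK_BOUNDS:
        scalars = qc_filter(scalars, bounds=tuple(config.qc_bounds))
        results._scalar = scalars
    wmti = results.wmti_maps(n_sphere=config.n_sphere)

    case_dir = out / "cases" / case.case_id
    gio.write_tensor_field(results.tensors, case_dir, affine)
    gio.write_maps(scalars, case_dir, affine)
    gio.write_maps(wmti, case_dir, affine)
    logger.info("case %s: fitted %d voxels, QC-deleted %d", case.case_id,
                results.n_fitted, scalars.n_qc_deleted)
    return roi_means(scalars, wmti, cbf, rois, case.case_id)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns paths of the written artifacts."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.resolved_yaml())

    if config.table is not None:
        table = gio.read_roi_table(config.table)
    else:
        if not config.cases:
            raise ValueError("no cases and no ROI table configured")
        rows = [process_case(c, config, out) for c in config.cases]
        table = pd.concat(rows, ignore_index=True)
        if config.markers is not None:
            markers = pd.read_csv(config.markers)
            keys = [k for k in ("case_id", "roi") if k in markers.columns]
            table = table.merge(markers, on=keys, how="left")
    table_path = out / "roi_table.csv"
    gio.write_roi_table(table, table_path)

    artifacts = {"table": str(table_path), "config": str(out / "config.yaml")}
    n_per_roi = table.groupby("roi")["case_id"].nunique()
    if n_per_roi.min() >= 3:
        comparisons, rocs = [], []
        for a, b in config.pairs:
            comparisons += compare_rois(table, a, b,
                                        alpha=config.alpha_comparisons)
            rocs += roc_analysis(table, a, b, n_boot=config.n_boot,
                                 seed=config.seed)
        correlations = []
        marker_cols = [c for c in ("Ki67_LI", "Bcl2_EA", "CD133_EA")
                       if c in table.columns]
        if marker_cols:
            for roi in (1, 2):
                correlations += marker_correlations(
                    table, roi, markers=marker_cols,
                    alpha=config.alpha_correlations,
                    n_boot=config.n_boot, seed=config.seed)
        frames, md = report(comparisons, rocs, correlations or None)
        for name, frame in frames.items():
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False)
            artifacts[name] = str(p)
        (out / "report.md").write_text(md)
        artifacts["report"] = str(out / "report.md")
    else:
        logger.info("fewer than 3 cases per ROI: statistics stage skipped")

    info = {"config_hash": config.digest(), "seed": config.seed,
            "n_cases": int(table["case_id"].nunique())}
    (out / "run_info.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    artifacts["run_info"] = str(out / "run_info.json")
    return artifacts
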