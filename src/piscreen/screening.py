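"""Batch screening driver and benchmark metrics.

``screen`` runs the gap ladder over a CSV manifest of structures and never
aborts on a single molecule: per-row failures (unsupported centers,
unreadable files, odd electron counts) become status fields, mirroring how
large screening campaigns report success rates rather than crashing.

The metric helpers reproduce the arithmetic of virtual-screening reports:
a confusion matrix over the inverted/normal classification (positive class
= inverted, i.e. reference gap < 0) and the derived accuracy, recall,
specificity, F1 and ROC-AUC, plus regression quality (R^2, Spearman rho,
RMSE) against reference gaps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .exceptions import PiscreenError
from .geometry import geometry_from_smiles, load_geometry
from .model import PPPModel
from .parameters import ValenceStateTable

logger = logging.getLogger(__name__)

#: columns of the screening output CSV, in order
OUTPUT_COLUMNS = [
    "id", "E_S1_eV", "E_T1_eV", "f_S1", "overlap_HL",
    "gap_scf", "dsp_scf", "gap_scf_dsp", "gap_cis", "dsp_cis",
    "gap_cis_dsp", "gap_cis_dsp_lc", "inverted", "warnings", "status",
]


@dataclass
class ScreeningRecord:
    molecule_id: str
    source: str
    status: str = "ok"
    warnings: list[str] = field(default_factory=list)
    gaps: object = None          # GapEstimates when status == "ok"
    inverted: bool | None = None

    def as_row(self) -> dict:
        row = {c: "" for c in OUTPUT_COLUMNS}
        row["id"] = self.molecule_id
        row["status"] = self.status
        row["warnings"] = ";".join(sorted(self.warnings))
        if self.gaps is not None:
            g = self.gaps
            row.update({
                "E_S1_eV": g.e_s1, "E_T1_eV": g.e_t1, "f_S1": g.f_s1,
                "overlap_HL": g.homo_lumo_overlap,
                "gap_scf": g.gap_scf, "dsp_scf": g.dsp_scf,
                "gap_scf_dsp": g.gap_scf_dsp, "gap_cis": g.gap_cis,
                "dsp_cis": g.dsp_cis, "gap_cis_dsp": g.gap_cis_dsp,
                "gap_cis_dsp_lc": g.gap_cis_dsp_lc,
                "inverted": bool(self.inverted),
            })
        return row


def screen_one(molecule_id: str, source: str,
               config: ScreenConfig | None = None,
               table: ValenceStateTable | None = None) -> ScreeningRecord:
    """Run the full ladder for one structure path (or SMILES string)."""
    config = config or ScreenConfig()
    record = ScreeningRecord(molecule_id, source)
    t0 = time.perf_counter()
    try:
        if Path(source).exists():
            geom = load_geometry(source)
        else:
            geom = geometry_from_smiles(source)
        model = PPPModel.from_geometry(
            geom, table=table, cutoff_scale=config.cutoff_scale,
            overlap_method=config.overlap_method)
        res = model.fit(tol=config.scf_tol, max_iter=config.scf_max_iter,
                        damping=config.scf_damping)
        gaps = res.gap_estimates(lc_slope=config.lc_slope,
                                 lc_intercept=config.lc_intercept,
                                 force=True)
        record.gaps = gaps
        record.warnings = sorted(gaps.warnings)
        level = config.classification_level
        record.inverted = gaps.inverted(
            level, use_lc=config.apply_linear_correction)
    except (PiscreenError, OSError, ValueError) as exc:
        record.status = f"failed:{type(exc).__name__}:{exc}"
    logger.debug("screened %s in %.1f ms", molecule_id,
                 1e3 * (time.perf_counter() - t0))
    return record


def screen(manifest: str | Path, config: ScreenConfig | None = None,
           out: str | Path | None = None) -> pd.DataFrame:
    """Screen every row of a manifest CSV (columns: id, structure_path or
    smiles, optional ref_gap_eV); returns (and optionally writes) one output
    row per manifest row, failures included."""
    config = config or ScreenConfig()
    table = (ValenceStateTable.from_csv(config.table_path)
             if config.table_path else None)
    df = pd.read_csv(manifest)
    if df.empty:
        result = pd.DataFrame(columns=OUTPUT_COLUMNS)
        if out is not None:
            result.to_csv(out, index=False)
        return result
    source_col = "structure_path" if "structure_path" in df.columns else "smiles"
    rows = []
    n_failed = 0
    for _, row in df.iterrows():
        rec = screen_one(str(row["id"]), str(row[source_col]), config, table)
        out_row = rec.as_row()
        if "ref_gap_eV" in df.columns and pd.notna(row.get("ref_gap_eV")):
            out_row["ref_gap_eV"] = float(row["ref_gap_eV"])
        rows.append(out_row)
        n_failed += rec.status != "ok"
    result = pd.DataFrame(rows)
    n = len(result)
    logger.info("screened %d molecules, %d failed (success rate %.2f%%)",
                n, n_failed, 100.0 * (n - n_failed) / n)
    if out is not None:
        result.to_csv(out, index=False)
    return result


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = inverted gap (< threshold)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred_gaps, ref_gaps, threshold: float = 0.0) -> ConfusionMatrix:
    pred = np.asarray(pred_gaps, dtype=float)
    ref = np.asarray(ref_gaps, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference lists differ in length")
    p = pred < threshold
    r = ref < threshold
    return ConfusionMatrix(
        tp=int(np.sum(p & r)), tn=int(np.sum(~p & ~r)),
        fp=int(np.sum(p & ~r)), fn=int(np.sum(~p & r)))


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, recall, specificity, F1 and ROC-AUC from a confusion matrix.

    For hard binary predictions the ROC-AUC equals the balanced accuracy
    (recall + specificity) / 2.  Undefined ratios (zero denominators) are
    reported as 0.0 with a flag.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    recall = _ratio(cm.tp, cm.tp + cm.fn, flags, "recall")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, flags, "specificity")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "recall": recall,
        "specificity": specificity,
        "f1": _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, flags, "f1"),
        "roc_auc": 0.5 * (recall + specificity),
        "flags": flags,
    }


def regression_metrics(pred, ref) -> dict:
    """Coefficient of determination R^2, Spearman rho and RMSE (eV)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("need two equal-length lists of at least 2 values")
    flags: list[str] = []
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        flags.append("r2_undefined")
        r2 = 0.0
    else:
        r2 = 1.0 - float(np.sum((pred - ref) ** 2)) / ss_tot
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        flags.append("spearman_undefined")
        rho = 0.0
    else:
        rho = float(stats.spearmanr(pred, ref).statistic)
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return {"r2": r2, "spearman_rho": rho, "rmse": rmse, "flags": flags}


def round_display(value: float, digits: int = 2) -> float:
    """Display rounding used in report tables (round-half-even).

    Ties at the last digit round to the even neighbour, matching how
    screening reports print e.g. an accuracy of 160/256 = 0.625 as 0.62.
    """
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def metric_report(results: pd.DataFrame, ref_col: str = "ref_gap_eV",
                  pred_col: str = "gap_cis_dsp",
                  threshold: float = 0.0) -> dict:
    """Combined regression + classification report from a screening table."""
    ok = results[(results["status"] == "ok") & results[ref_col].notna()]
    pred = ok[pred_col].astype(float).to_numpy()
    ref = ok[ref_col].astype(float).to_numpy()
    cm = confusion(pred, ref, threshold)
    out = {"n": int(len(ok)),
           "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}}
    out.update(classification_metrics(cm))
    if len(ok) >= 2:
        out.update(regression_metrics(pred, ref))
    return out
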