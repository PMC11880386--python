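"""Readers, writers, and the pipeline entry point.

Formats
-------
Expression matrix: TSV/CSV with gene ids in the first column and one
column per sample, accompanied by a two-column sample sheet
(sample_id, group). Gene ids are matched case-insensitively against the
panel; panel genes absent from the file are reported, not fatal.

Cohort table: CSV with columns patient_id, tps, btv, response and
optionally os_months, event. TPS must lie in [0, 100], BTV must be > 0.

Reports are JSON with full-precision numbers; rounding for display
happens only at comparison/presentation time.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hiskit import presets
from hiskit.cohort import (
    empirical_roc,
    delong_test,
    fit_bivariate,
    reconstruct_joint_table,
    reconstruct_tps_table,
)
from hiskit.expression import (
    DEFAULT_PANEL,
    ExpressionMatrix,
    GenePanel,
    classify_his,
    compute_fold_changes,
    count_directional,
)

__all__ = [
    "ReadReport",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_cohort",
    "run_pipeline",
]


@dataclass
class ReadReport:
    """What matched (and what did not) while reading an expression matrix."""

    n_genes_matched: int
    panel_genes_missing: list[str] = field(default_factory=list)
    extra_genes_ignored: list[str] = field(default_factory=list)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    panel: GenePanel | None = None,
) -> tuple[ExpressionMatrix, ReadReport]:
    """Read a gene x sample FPKM matrix plus its sample sheet.

    Returns the validated matrix (rows restricted and ordered to the panel
    genes found in the file) and a :class:`ReadReport` listing panel genes
    the file lacks and file genes outside the panel.
    """
    if panel is None:
        panel = DEFAULT_PANEL
    raw = _read_table(matrix_path)
    if raw.shape[1] < 2:
        raise ValueError("expression matrix needs a gene column plus >= 1 sample")
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str)
    if genes.str.lower().duplicated().any():
        dups = genes[genes.str.lower().duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dups}")

    values = raw.drop(columns=[gene_col])
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cells in {matrix_path}: {exc}") from exc

    sheet = _read_table(sample_sheet_path)
    if sheet.shape[1] < 2:
        raise ValueError("sample sheet needs columns (sample_id, group)")
    sheet_ids = sheet.iloc[:, 0].astype(str)
    if sheet_ids.duplicated().any():
        raise ValueError("duplicate sample ids in the sample sheet")
    groups = dict(zip(sheet_ids, sheet.iloc[:, 1].astype(str)))
    missing_samples = [c for c in values.columns if c not in groups]
    if missing_samples:
        raise ValueError(f"samples absent from the sample sheet: {missing_samples}")

    by_lower = {g.lower(): i for i, g in enumerate(genes)}
    matched, missing = [], []
    for pg in panel.gene_ids:
        (matched if pg.lower() in by_lower else missing).append(pg)
    if missing:
        warnings.warn(
            f"panel genes not found in {matrix_path}: {missing}", stacklevel=2
        )
    extra = [g for g in genes if g.lower() not in {p.lower() for p in panel.gene_ids}]

    sub_panel = panel.subset(matched)
    rows = [by_lower[g.lower()] for g in sub_panel.gene_ids]
    matrix = ExpressionMatrix(
        panel=sub_panel,
        sample_ids=tuple(values.columns),
        group_labels={c: groups[c] for c in values.columns},
        values=values.to_numpy(dtype=float)[rows, :],
    )
    report = ReadReport(
        n_genes_matched=len(matched),
        panel_genes_missing=missing,
        extra_genes_ignored=extra,
    )
    return matrix, report


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path) -> None:
    """Write a matrix + sample sheet in the dialect read_expression reads."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    frame.to_csv(matrix_path, sep=sep)
    sheet = pd.DataFrame({
        "sample_id": list(matrix.sample_ids),
        "group": [matrix.group_labels[s] for s in matrix.sample_ids],
    })
    sep = "\t" if str(sample_sheet_path).endswith((".tsv", ".txt")) else ","
    sheet.to_csv(sample_sheet_path, sep=sep, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient cohort CSV.

    Required columns: patient_id, tps, btv, response. Optional:
    os_months, event (both required together for survival analyses).
    """
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"cohort file {path} contains no patients")
    required = {"patient_id", "tps", "btv", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids")
    tps = df["tps"].astype(float)
    if ((tps < 0) | (tps > 100)).any():
        raise ValueError("tps values must lie in [0, 100]")
    if (df["btv"].astype(float) <= 0).any():
        raise ValueError("btv values must be > 0")
    if not df["response"].isin((0, 1)).all():
        raise ValueError("response must be 0/1")
    if ("os_months" in df.columns) != ("event" in df.columns):
        raise ValueError("os_months and event must be supplied together")
    if "os_months" in df.columns:
        if (df["os_months"].astype(float) < 0).any():
            raise ValueError("os_months must be >= 0")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event must be 0/1")
    return df


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Any of the three input blocks may be omitted; the corresponding stage
    is then skipped. Paths are resolved at run time.
    """

    out_dir: str | Path
    expression_matrix: str | Path | None = None
    sample_sheet: str | Path | None = None
    baseline_group: str = "small"
    comparison_group: str = "large"
    fc_cut: float = 2.0
    high_min: int = 10
    low_max: int = 5
    pseudocount: float = 0.01
    cohort: str | Path | None = None
    tps_cut: int = 50
    btv_cut: float = presets.BTV_CUTOFF
    seed: int = 0

    def validate(self) -> None:
        if not self.low_max < self.high_min:
            raise ValueError("low_max must be < high_min")
        if self.fc_cut <= 1:
            raise ValueError("fc_cut must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.tps_cut not in presets.TPS_CUTS:
            raise ValueError(f"tps_cut must be one of {presets.TPS_CUTS}")
        if (self.expression_matrix is None) != (self.sample_sheet is None):
            raise ValueError("expression_matrix and sample_sheet go together")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def score_expression(matrix: ExpressionMatrix, baseline_group: str,
                     comparison_group: str, fc_cut: float = 2.0,
                     high_min: int = 10, low_max: int = 5,
                     pseudocount: float = 0.01) -> dict:
    """HIS scoring report: per-gene FC, directional counts, and the call."""
    profile = compute_fold_changes(matrix, baseline_group, comparison_group,
                                   pseudocount=pseudocount)
    call = classify_his(profile, fc_cut=fc_cut, high_min=high_min, low_max=low_max)
    n_up, n_down = count_directional(profile, up_cut=fc_cut)
    return {
        "baseline_group": baseline_group,
        "comparison_group": comparison_group,
        "pseudocount": pseudocount,
        "fold_changes": {g: float(f) for g, f in zip(profile.gene_ids, profile.fc)},
        "n_genes_fc_ge_cut": call.n_genes_fc_ge_cut,
        "n_up": n_up,
        "n_down": n_down,
        "label": call.label.value,
        "fc_cut": fc_cut,
        "high_min": high_min,
        "low_max": low_max,
    }


def predict_cohort(cohort: pd.DataFrame, tps_cut: int = 50,
                   btv_cut: float = presets.BTV_CUTOFF,
                   refit: bool = False) -> dict:
    """TPS-alone vs TPS+BTV prediction report on a patient table.

    Scores every patient with the TPS indicator and with the bivariate
    logistic model (published coefficients by default, or refit to the
    cohort with ``refit=True``), and compares the two AUCs by DeLong's
    test.
    """
    labels = cohort["response"].to_numpy(dtype=int)
    tps_pos = (cohort["tps"].to_numpy(dtype=float) >= tps_cut)
    btv_small = (cohort["btv"].to_numpy(dtype=float) <= btv_cut)

    model = presets.REFERENCE_MODELS[tps_cut]
    if refit:
        from hiskit.cohort import JointTable2x2x2

        cells = {}
        for b in (True, False):
            for t in (True, False):
                in_cell = (btv_small == b) & (tps_pos == t)
                cells[(b, t)] = (int(labels[in_cell].sum()),
                                 int((1 - labels[in_cell]).sum()))
        model = fit_bivariate(JointTable2x2x2(cells=cells), tps_cut=tps_cut)

    tps_scores = tps_pos.astype(float)
    biv_scores = model.logit(btv_small, tps_pos)
    roc_tps = empirical_roc(tps_scores, labels)
    roc_biv = empirical_roc(biv_scores, labels)
    dl = delong_test(biv_scores, tps_scores, labels)
    from hiskit.cohort import sens_spec_at

    sens_t, spec_t = sens_spec_at(tps_scores, labels, 1.0)
    # combined positive region: every cell above the lowest-logit cell
    biv_threshold = model.intercept + min(model.coef_btv, model.coef_tps)
    sens_b, spec_b = sens_spec_at(biv_scores, labels, biv_threshold - 1e-9)
    return {
        "n_patients": int(len(cohort)),
        "tps_cut": tps_cut,
        "btv_cut": btv_cut,
        "model": {"intercept": model.intercept, "coef_btv": model.coef_btv,
                  "coef_tps": model.coef_tps, "refit": refit},
        "auc_tps": roc_tps.auc,
        "auc_bivariate": roc_biv.auc,
        "sens_spec_tps": [sens_t, spec_t],
        "sens_spec_bivariate": [sens_b, spec_b],
        "delong": {"z": dl.z, "p": dl.p, "degenerate": dl.degenerate},
    }


def reconstruct_report(tps_cut: int = 50) -> dict:
    """Rebuild the reference cohort's 2x2 and 2x2x2 tables at one TPS cut."""
    margins = presets.TABLE1_MARGINS
    sens, spec = presets.UNIVARIATE_SENS_SPEC[tps_cut]
    tps_table = reconstruct_tps_table(
        margins.n_resp, margins.n_nonresp, sens, spec,
        expected_positive_total=margins.tps_positive_total(tps_cut),
    )
    c_sens, c_spec = presets.COMBINED_SENS_SPEC[tps_cut]
    joint = reconstruct_joint_table(margins, tps_cut, tps_table, c_sens, c_spec)
    model = presets.REFERENCE_MODELS[tps_cut]
    refit = fit_bivariate(joint, tps_cut=tps_cut)
    scores, labels = joint.scores(model)
    return {
        "tps_cut": tps_cut,
        "tps_table": dataclasses.asdict(tps_table),
        "auc_tps": tps_table.auc,
        "joint_cells": {f"small={b},tps_pos={t}": list(c)
                        for (b, t), c in sorted(joint.cells.items(), reverse=True)},
        "auc_bivariate": empirical_roc(scores, labels).auc,
        "auc_small_stratum": joint.stratum(True).auc,
        "auc_large_stratum": joint.stratum(False).auc,
        "published_model": {"intercept": model.intercept,
                            "coef_btv": model.coef_btv, "coef_tps": model.coef_tps},
        "refit_model": {"intercept": refit.intercept,
                        "coef_btv": refit.coef_btv, "coef_tps": refit.coef_tps},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write a JSON report bundle.

    The report embeds the full parameter set and the package version, and
    is byte-identical across reruns with the same inputs and seed.
    """
    from hiskit import __version__

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "package_version": __version__,
        # out_dir is where the report lands, not an analysis parameter
        "parameters": _jsonable({
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"
        }),
    }

    if config.expression_matrix is not None:
        matrix, read_rep = read_expression(config.expression_matrix,
                                           config.sample_sheet)
        report["expression"] = score_expression(
            matrix, config.baseline_group, config.comparison_group,
            fc_cut=config.fc_cut, high_min=config.high_min,
            low_max=config.low_max, pseudocount=config.pseudocount,
        )
        report["expression"]["read_report"] = _jsonable(read_rep)

    if config.cohort is not None:
        cohort = read_cohort(config.cohort)
        report["prediction"] = predict_cohort(cohort, tps_cut=config.tps_cut,
                                              btv_cut=config.btv_cut)
        if "os_months" in cohort.columns:
            from hiskit.survival import cox_binary, logrank_test

            groups = (cohort["tps"].astype(float) >= config.tps_cut).astype(int)
            chi2, p = logrank_test(cohort["os_months"], cohort["event"], groups)
            cox = cox_binary(cohort["os_months"], cohort["event"], groups)
            report["survival"] = {
                "stratify": f"tps>={config.tps_cut}",
                "logrank_chi2": chi2,
                "logrank_p": p,
                "hr": cox.hr,
                "ci": [cox.ci_low, cox.ci_high],
            }

    report["reconstruction"] = reconstruct_report(config.tps_cut)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
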