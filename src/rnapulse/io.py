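"""Flat-file I/O: TSV matrices with a JSON sidecar, fitted-parameter
tables, truth records and recovery metrics.

TSVs are genes x time (header row = times in minutes) and round-trip at
full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TimeCourseExpression
from .estimate import FitConfig, FitResult
from .kinetics import GeneKinetics, ScaleFactors, TimeGrid
from .pulse import PulseParams

__all__ = [
    "write_expression", "read_expression",
    "write_fit", "read_fit",
    "write_truth", "read_truth",
]

_FLOAT_FMT = "%.17g"

PARAM_COLS = [
    f"{curve}_{p}"
    for curve in ("alpha", "gamma", "beta")
    for p in ("h0", "h1", "h2", "t1", "t2", "slope")
]


def write_expression(expr: TimeCourseExpression, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("P", "T", "TL"):
        getattr(expr, name).to_csv(
            outdir / f"{name}.tsv", sep="\t", float_format=_FLOAT_FMT,
            index_label="gene",
        )
    side = {
        "times": list(map(float, expr.grid.times)),
        "tL": float(expr.grid.tL),
        "unit": expr.unit,
        "normalization": expr.normalization,
        "gene_flags": expr.gene_flags,
    }
    libs = getattr(expr, "library_sizes", None)
    if libs is not None:
        side["library_sizes"] = {
            k: list(map(float, v)) for k, v in libs.items()
        }
    (outdir / "expression.json").write_text(json.dumps(side, indent=1))


def read_expression(indir) -> TimeCourseExpression:
    indir = Path(indir)
    side = json.loads((indir / "expression.json").read_text())
    times = np.asarray(side["times"], dtype=float)
    mats = {}
    for name in ("P", "T", "TL"):
        df = pd.read_csv(indir / f"{name}.tsv", sep="\t", index_col="gene",
                         float_precision="round_trip")
        df.columns = list(times)
        mats[name] = df
    return TimeCourseExpression(
        P=mats["P"], T=mats["T"], TL=mats["TL"],
        grid=TimeGrid(times=times, tL=side["tL"]),
        unit=side.get("unit", "counts"),
        normalization=side.get("normalization", "none"),
        gene_flags=side.get("gene_flags", {}),
    )


def _kin_row(kin: GeneKinetics) -> list:
    vals = []
    for th in (kin.theta_alpha, kin.theta_gamma, kin.theta_beta):
        vals += list(th.as_array())
    return vals + [kin.P0, kin.T0, kin.J, kin.chi2_stat, kin.chi2_p, kin.dof]


def write_fit(fits: FitResult, outdir) -> None:
    """params.tsv (one row per gene, fixed column order) and
    scale_factors.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = PARAM_COLS + ["P0", "T0", "J", "chi2_stat", "chi2_p", "dof"]
    rows, idx, statuses = [], [], []
    for g in fits.genes:
        idx.append(g)
        statuses.append(fits.status.get(g, "failed"))
        if g in fits.kinetics:
            rows.append(_kin_row(fits.kinetics[g]))
        else:
            rows.append([np.nan] * len(cols))
    df = pd.DataFrame(rows, index=pd.Index(idx, name="gene"), columns=cols)
    df["status"] = statuses
    df.to_csv(outdir / "params.tsv", sep="\t", float_format=_FLOAT_FMT)
    sf = fits.scale_factors
    (outdir / "scale_factors.json").write_text(
        json.dumps({"c1": sf.c1, "c2": sf.c2}, indent=1)
    )


def read_fit(indir, config: FitConfig | None = None) -> FitResult:
    indir = Path(indir)
    df = pd.read_csv(indir / "params.tsv", sep="\t", index_col="gene",
                     float_precision="round_trip")
    sfd = json.loads((indir / "scale_factors.json").read_text())
    kinetics, status = {}, {}
    for g, row in df.iterrows():
        status[g] = row["status"]
        if row["status"] in ("ok", "refit") and np.isfinite(row["alpha_h0"]):
            thetas = [
                PulseParams.from_array(
                    [row[f"{c}_{p}"] for p in ("h0", "h1", "h2", "t1", "t2", "slope")]
                )
                for c in ("alpha", "gamma", "beta")
            ]
            kinetics[g] = GeneKinetics(
                theta_alpha=thetas[0], theta_gamma=thetas[1], theta_beta=thetas[2],
                P0=float(row["P0"]), T0=float(row["T0"]), J=float(row["J"]),
                chi2_stat=float(row["chi2_stat"]), chi2_p=float(row["chi2_p"]),
                dof=int(row["dof"]) if np.isfinite(row["dof"]) else 0,
            )
    return FitResult(
        genes=list(df.index), kinetics=kinetics, status=status,
        scale_factors=ScaleFactors(c1=float(sfd["c1"]), c2=float(sfd["c2"])),
        config=config or FitConfig(),
    )


def write_truth(truth, path) -> None:
    from .simulate import SimTruth  # noqa: F401  (type reference)

    cfg = truth.config
    payload = {
        "genes": truth.genes,
        "theta_alpha": truth.theta_alpha.tolist(),
        "theta_gamma_k": truth.theta_gamma_k.tolist(),
        "theta_beta_k": truth.theta_beta_k.tolist(),
        "P0": truth.P0.tolist(),
        "T0": truth.T0.tolist(),
        "scale_factors": {"c1": truth.scale_factors.c1, "c2": truth.scale_factors.c2},
        "seed": truth.seed,
        "config": {
            "n_genes": cfg.n_genes, "times": list(map(float, cfg.times)),
            "tL": cfg.tL, "mu": cfg.mu, "sigma": cfg.sigma, "kt": cfg.kt,
            "noise_cv": cfg.noise_cv, "c1": cfg.c1, "c2": cfg.c2,
            "seed": cfg.seed, "rk4_step": cfg.rk4_step,
            "slope_range": list(cfg.slope_range),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path):
    from .simulate import SimConfig, SimTruth

    d = json.loads(Path(path).read_text())
    c = d["config"]
    cfg = SimConfig(
        n_genes=c["n_genes"], times=np.asarray(c["times"]), tL=c["tL"],
        mu=c["mu"], sigma=c["sigma"], kt=c["kt"], noise_cv=c["noise_cv"],
        c1=c["c1"], c2=c["c2"], seed=c["seed"], rk4_step=c["rk4_step"],
        slope_range=tuple(c["slope_range"]),
    )
    return SimTruth(
        genes=d["genes"],
        theta_alpha=np.asarray(d["theta_alpha"]),
        theta_gamma_k=np.asarray(d["theta_gamma_k"]),
        theta_beta_k=np.asarray(d["theta_beta_k"]),
        P0=np.asarray(d["P0"]), T0=np.asarray(d["T0"]),
        scale_factors=ScaleFactors(**d["scale_factors"]),
        config=cfg, seed=d["seed"],
    )
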