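"""Statistical validation of fascicle localization.

Angular CoM positions are analysed with a balanced two-way ANOVA (factors:
fascicle type and measurement technique).  Cluster tightness is summarised
by the scatter metric: per (fascicle, technique), the SD of x and y around
the cluster mean, averaged over the axes and then over fascicles, giving
one scatter value per technique (µm, also expressed as % of nerve
diameter).  Angles are treated as linear after rotating the frame so that
no cluster straddles the 0°/360° wrap.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    pass


@dataclass
class ValidationReport:
    anova: pd.DataFrame
    scatter: pd.DataFrame
    mean_positions: pd.DataFrame
    pass_flags: dict[str, bool]
    thresholds: dict[str, float]
    provenance: dict

    def to_json_dict(self) -> dict:
        return dict(
            anova=self.anova.to_dict(orient="records"),
            scatter=self.scatter.to_dict(orient="records"),
            mean_positions=self.mean_positions.to_dict(orient="records"),
            pass_flags=self.pass_flags,
            thresholds=self.thresholds,
            provenance=self.provenance,
        )


def _unwrap_angles(theta: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Rotate the angular frame so no cluster straddles 0/360: place the cut
    in the widest empty gap of the pooled angles, then assert every cluster
    spans < 180°."""
    th = np.mod(np.asarray(theta, dtype=float), 360.0)
    order = np.argsort(th)
    sorted_th = th[order]
    gaps = np.diff(np.concatenate([sorted_th, [sorted_th[0] + 360.0]]))
    cut = sorted_th[np.argmax(gaps)] + gaps.max() / 2.0
    out = np.mod(th - cut, 360.0)
    for g in np.unique(groups):
        span = out[groups == g].max() - out[groups == g].min()
        if span >= 180.0:
            raise DesignError(
                f"cluster {g!r} spans {span:.0f}° after unwrapping; angular "
                "ANOVA on a linear scale is not meaningful"
            )
    return out


def two_way_anova(theta, fascicle, technique, interaction: bool = True) -> pd.DataFrame:
    """Balanced two-way ANOVA of angular CoM position.

    Standard sum-of-squares decomposition with factors A = fascicle and
    B = technique; the interaction term is included when each cell has
    replicates.  Returns a table with (factor, df, SS, MS, F, p).
    """
    th = np.asarray(theta, dtype=float)
    A = np.asarray(fascicle)
    B = np.asarray(technique)
    if th.size != A.size or th.size != B.size:
        raise ValueError("inputs must have equal length")
    a_levels, b_levels = np.unique(A), np.unique(B)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise DesignError("need at least two levels per factor")

    cells = {}
    for ai in a_levels:
        for bi in b_levels:
            cells[(ai, bi)] = th[(A == ai) & (B == bi)]
    ns = {k: len(v) for k, v in cells.items()}
    n_rep = next(iter(ns.values()))
    if n_rep < 1 or len(set(ns.values())) != 1:
        raise DesignError("unbalanced design: unequal or empty cells")

    y = _unwrap_angles(th, np.char.add(A.astype(str), B.astype(str)))
    cells = {
        k: y[(A == k[0]) & (B == k[1])] for k in cells
    }
    if np.allclose(np.std(y), 0.0):
        raise DesignError("all observations equal; F undefined")

    grand = y.mean()
    p, q, n = len(a_levels), len(b_levels), n_rep
    N = p * q * n
    ss_total = float(np.sum((y - grand) ** 2))
    a_means = {ai: y[A == ai].mean() for ai in a_levels}
    b_means = {bi: y[B == bi].mean() for bi in b_levels}
    ss_a = float(q * n * sum((a_means[ai] - grand) ** 2 for ai in a_levels))
    ss_b = float(p * n * sum((b_means[bi] - grand) ** 2 for bi in b_levels))
    cell_means = {k: v.mean() for k, v in cells.items()}
    ss_cells = float(n * sum((cell_means[k] - grand) ** 2 for k in cells))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells

    rows = []
    use_inter = interaction and n > 1
    df_a, df_b = p - 1, q - 1
    df_ab = (p - 1) * (q - 1)
    if use_inter:
        df_err = N - p * q
    else:
        ss_err = ss_err + ss_ab
        df_err = N - p * q + df_ab
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    def row(name, df_f, ss):
        ms = ss / df_f
        F = ms / ms_err if ms_err > 0 else np.inf
        pval = float(stats.f.sf(F, df_f, df_err)) if np.isfinite(F) else 0.0
        return dict(factor=name, df=df_f, SS=ss, MS=ms, F=F, p=pval)

    rows.append(row("fascicle", df_a, ss_a))
    rows.append(row("technique", df_b, ss_b))
    if use_inter:
        rows.append(row("fascicle:technique", df_ab, ss_ab))
    rows.append(
        dict(factor="error", df=df_err, SS=ss_err, MS=ms_err, F=np.nan, p=np.nan)
    )
    rows.append(
        dict(factor="total", df=N - 1, SS=ss_total, MS=np.nan, F=np.nan, p=np.nan)
    )
    return pd.DataFrame(rows)


def scatter_metric(coms: pd.DataFrame, nerve_diameter_um: float = 1400.0) -> pd.DataFrame:
    """Per-technique scatter: SD of x and y around each (fascicle, technique)
    cluster mean, averaged over axes, then over fascicles.

    `coms` needs columns x_um, y_um, label, technique.  Singleton clusters
    are omitted (with a note in the result attrs).
    """
    rows, skipped = [], []
    for (label, tech), grp in coms.groupby(["label", "technique"]):
        if len(grp) < 2:
            skipped.append((label, tech))
            continue
        sx = grp["x_um"].std(ddof=1)
        sy = grp["y_um"].std(ddof=1)
        rows.append(dict(label=label, technique=tech, scatter_um=0.5 * (sx + sy)))
    per_cluster = pd.DataFrame(rows)
    if per_cluster.empty:
        raise DesignError("no cluster has >= 2 observations")
    out = (
        per_cluster.groupby("technique")["scatter_um"].mean().reset_index()
    )
    out["scatter_pct_diameter"] = 100.0 * out["scatter_um"] / nerve_diameter_um
    out.attrs["skipped_clusters"] = skipped
    out.attrs["per_cluster"] = per_cluster
    return out


def build_report(
    coms: pd.DataFrame,
    config: dict | None = None,
    nerve_diameter_um: float = 1400.0,
    out_dir: str | Path | None = None,
    thresholds: dict[str, float] | None = None,
    seeds: dict | None = None,
    make_figure: bool = True,
) -> ValidationReport:
    """Assemble the validation report (ANOVA + scatter + mean positions),
    write JSON/CSV/figure artifacts when ``out_dir`` is given, and evaluate
    configured pass/fail thresholds."""
    required = {"label", "technique", "theta_deg", "x_um", "y_um"}
    missing = required - set(coms.columns)
    if missing:
        raise ValueError(f"CoM table lacks columns: {sorted(missing)}")
    thresholds = thresholds or {"fascicle_p_max": 0.01, "technique_p_min": 0.05}
    config = config or {}

    anova = two_way_anova(coms["theta_deg"], coms["label"], coms["technique"])
    scatter = scatter_metric(coms, nerve_diameter_um)
    mean_pos = (
        coms.groupby(["label", "technique"])[["x_um", "y_um", "r_um", "theta_deg"]]
        .mean()
        .reset_index()
        if "r_um" in coms.columns
        else coms.groupby(["label", "technique"])[["x_um", "y_um", "theta_deg"]]
        .mean()
        .reset_index()
    )

    p_fasc = float(anova.loc[anova.factor == "fascicle", "p"].iloc[0])
    p_tech = float(anova.loc[anova.factor == "technique", "p"].iloc[0])
    flags = {
        "fascicle_separation_significant": p_fasc < thresholds["fascicle_p_max"],
        "technique_effect_nonsignificant": p_tech > thresholds["technique_p_min"],
    }

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    provenance = dict(config_hash=cfg_hash, seeds=seeds or {}, config=config)

    report = ValidationReport(
        anova=anova,
        scatter=scatter,
        mean_positions=mean_pos,
        pass_flags=flags,
        thresholds=thresholds,
        provenance=provenance,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        anova.to_csv(out_dir / "anova.csv", index=False)
        scatter.to_csv(out_dir / "scatter.csv", index=False)
        coms.to_csv(out_dir / "coms.csv", index=False)
        with open(out_dir / "report.json", "w") as f:
            json.dump(report.to_json_dict(), f, indent=2, sort_keys=True, default=float)
        if make_figure:
            _com_figure(coms, nerve_diameter_um, out_dir / "coms.png")
    return report


def _com_figure(coms: pd.DataFrame, nerve_diameter_um: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"tibial": "tab:red", "peroneal": "tab:green", "sural": "tab:blue"}
    markers = {"EIT": "o", "microct": "s", "histology": "^"}
    fig, ax = plt.subplots(figsize=(5, 5))
    R = nerve_diameter_um / 2.0
    circle = plt.Circle((0, 0), R, fill=False, color="k")
    ax.add_patch(circle)
    ax.annotate(
        "fiducial", xy=(0, R), xytext=(0, R * 1.15),
        ha="center", arrowprops=dict(arrowstyle="->"),
    )
    for (label, tech), grp in coms.groupby(["label", "technique"]):
        ax.scatter(
            grp["x_um"], grp["y_um"],
            c=colors.get(label, "gray"), marker=markers.get(tech, "x"),
            label=f"{label}/{tech}", s=30, alpha=0.8,
        )
    ax.set_xlim(-1.3 * R, 1.3 * R)
    ax.set_ylim(-1.3 * R, 1.3 * R)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
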