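"""Per-complex stoichiometries, time-course summaries and the statistical
comparisons used on them.

Molecule "size" means the number of subunits per molecule; the molar ratio
of a complex is sHsp subunits divided by client subunits.  Size
distributions are compared non-parametrically (Kruskal-Wallis with Dunn's
post-hoc z-tests, Holm-adjusted by default); colocalised vs non-colocalised
sizes over time are compared with a two-way ANOVA on log10 sizes and
Tukey HSD per timepoint.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError
from .types import ComplexRecord, MoleculeSize

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# complex table assembly


def build_complex_table(
    client_sizes: dict[int, MoleculeSize],
    shsp_sizes: dict[int, MoleculeSize],
    pairs: list[tuple[int, int, float]],
    timepoint_h: float,
    replicate: str,
) -> list[ComplexRecord]:
    """One record per client molecule: colocalised records join the paired
    sHsp size; unpaired clients carry the client size only.

    Sizes must already carry channel-appropriate I_step and labelling
    corrections.  Pairs referencing a rejected (missing) trajectory are
    dropped with a logged reason.
    """
    paired_shsp = {}
    for ci, si, dist in pairs:
        if ci not in client_sizes:
            logger.warning(
                "dropping pair (client %d, shsp %d): client trajectory rejected", ci, si
            )
            continue
        if si not in shsp_sizes:
            logger.warning(
                "dropping pair (client %d, shsp %d): shsp trajectory rejected", ci, si
            )
            continue
        paired_shsp[ci] = (si, dist)

    records = []
    for ci, csize in sorted(client_sizes.items()):
        if ci in paired_shsp:
            si, dist = paired_shsp[ci]
            records.append(
                ComplexRecord(
                    timepoint_h=timepoint_h,
                    replicate=replicate,
                    client_subunits=csize.subunits_corrected,
                    shsp_subunits=shsp_sizes[si].subunits_corrected,
                    colocalised=True,
                    pair_distance_px=dist,
                )
            )
        else:
            records.append(
                ComplexRecord(
                    timepoint_h=timepoint_h,
                    replicate=replicate,
                    client_subunits=csize.subunits_corrected,
                )
            )
    return records


def records_to_frame(records: list[ComplexRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "timepoint_h": r.timepoint_h,
                "replicate": r.replicate,
                "client_subunits": r.client_subunits,
                "shsp_subunits": r.shsp_subunits,
                "colocalised": r.colocalised,
                "molar_ratio": r.molar_ratio,
                "pair_distance_px": r.pair_distance_px,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "timepoint_h",
            "replicate",
            "client_subunits",
            "shsp_subunits",
            "colocalised",
            "molar_ratio",
            "pair_distance_px",
        ],
    )


# --------------------------------------------------------------------------
# time-course summaries


def bootstrap_se_median(
    x: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Bootstrap standard error of the median (seeded)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    meds = np.median(x[idx], axis=1)
    return float(np.std(meds, ddof=1))


def summarize_timecourse(
    records: list[ComplexRecord] | pd.DataFrame,
    coloc_fractions: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-timepoint summary: percent colocalised (mean +/- SD over
    replicates, from the chance-corrected per-field fractions), median molar
    ratio, and median subunits per molecule split by colocalisation state
    with bootstrap SE of the median.

    ``coloc_fractions`` is an optional frame with columns
    (timepoint_h, replicate, corrected_fraction); when absent, the percent
    colocalised falls back to the per-replicate fraction of colocalised
    records (uncorrected for chance).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise InvalidInputError("no records to summarise")

    rows = []
    for tp, g in df.groupby("timepoint_h"):
        if coloc_fractions is not None:
            fr = coloc_fractions.loc[
                coloc_fractions["timepoint_h"] == tp, "corrected_fraction"
            ].to_numpy(dtype=float)
        else:
            fr = g.groupby("replicate")["colocalised"].mean().to_numpy(dtype=float)
        ratios = g["molar_ratio"].dropna().to_numpy(dtype=float)
        coloc_sizes = g.loc[g["colocalised"], "client_subunits"].to_numpy(dtype=float)
        free_sizes = g.loc[~g["colocalised"], "client_subunits"].to_numpy(dtype=float)
        row = {
            "timepoint_h": tp,
            "n_molecules": len(g),
            "percent_colocalised": 100.0 * float(np.mean(fr)) if len(fr) else np.nan,
            "percent_colocalised_sd": 100.0 * float(np.std(fr, ddof=1))
            if len(fr) > 1
            else np.nan,
            "median_molar_ratio": float(np.median(ratios)) if len(ratios) else np.nan,
        }
        for name, vals in (("coloc", coloc_sizes), ("noncoloc", free_sizes)):
            if len(vals):
                row[f"median_subunits_{name}"] = float(np.median(vals))
                row[f"median_subunits_{name}_se"] = bootstrap_se_median(
                    vals, n_boot=n_boot, seed=seed
                )
            else:
                logger.warning("timepoint %s h: no %s molecules", tp, name)
                row[f"median_subunits_{name}"] = np.nan
                row[f"median_subunits_{name}_se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("timepoint_h").reset_index(drop=True)


# --------------------------------------------------------------------------
# Kruskal-Wallis with Dunn's procedure


def dunn_test(
    groups: list[np.ndarray], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    For groups i, j:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups.  Two-sided p-values
    are adjusted by ``adjust`` in {"holm", "bonferroni", "none"}.
    """
    ns = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + ns)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z, "p_unadjusted": p})
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["p_adjusted"] = out["p_unadjusted"]
    elif adjust in ("holm", "bonferroni"):
        out["p_adjusted"] = multipletests(out["p_unadjusted"], method=adjust)[1]
    else:
        raise InvalidInputError(f"unknown adjustment {adjust!r}")
    return out


def compare_distributions(
    groups: list[np.ndarray], adjust: str = "holm"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test (tie-corrected) followed by Dunn's
    pairwise procedure.  Returns (H, omnibus p, pairwise table)."""
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for k, g in enumerate(arrays):
        if len(g) < 2:
            raise InvalidInputError(f"group {k} has fewer than 2 observations")
    h, p = stats.kruskal(*arrays)
    pairwise = dunn_test(arrays, adjust=adjust)
    return float(h), float(p), pairwise


# --------------------------------------------------------------------------
# two-way ANOVA over colocalisation state x timepoint


def compare_sizes_over_time(
    records: list[ComplexRecord] | pd.DataFrame,
    size_column: str = "client_subunits",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (colocalisation state x timepoint) on log10 molecule
    sizes, with Tukey HSD between states within each timepoint.

    Returns (anova table, per-timepoint Tukey table).  Raises when any
    design cell has fewer than 2 observations, naming the cell.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.loc[:, ["timepoint_h", "colocalised", size_column]].dropna().copy()
    if df["colocalised"].nunique() < 2 or df["timepoint_h"].nunique() < 2:
        raise InvalidInputError("need >= 2 levels of both state and timepoint")
    counts = df.groupby(["timepoint_h", "colocalised"]).size()
    for (tp, st), n in counts.items():
        if n < 2:
            raise InvalidInputError(
                f"cell (timepoint={tp} h, colocalised={st}) has {n} observation(s)"
            )
    for tp in df["timepoint_h"].unique():
        sub = df[df["timepoint_h"] == tp]
        if sub["colocalised"].nunique() < 2:
            raise InvalidInputError(
                f"cell (timepoint={tp} h) lacks one colocalisation state"
            )

    if np.any(df[size_column] <= 0):
        raise InvalidInputError("sizes must be positive for the log10 transform")
    df["log_size"] = np.log10(df[size_column])
    df["state"] = np.where(df["colocalised"], "coloc", "noncoloc")
    model = ols("log_size ~ C(state) * C(timepoint_h)", data=df).fit()
    table = anova_lm(model, typ=2)

    rows = []
    for tp, g in df.groupby("timepoint_h"):
        a = g.loc[g["state"] == "coloc", "log_size"].to_numpy()
        b = g.loc[g["state"] == "noncoloc", "log_size"].to_numpy()
        res = stats.tukey_hsd(a, b)
        rows.append(
            {
                "timepoint_h": tp,
                "mean_diff_log10": float(a.mean() - b.mean()),
                "p_value": float(res.pvalue[0, 1]),
            }
        )
    return table, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plain-table exports for plotting


def hexbin_table(
    x: np.ndarray, y: np.ndarray, gridsize: int = 20
) -> pd.DataFrame:
    """2-D histogram as a plain table (bin centres, count, density), so
    plotting is decoupled from analysis."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    counts, xe, ye = np.histogram2d(x, y, bins=gridsize)
    xc = (xe[:-1] + xe[1:]) / 2
    yc = (ye[:-1] + ye[1:]) / 2
    xs, ys = np.meshgrid(xc, yc, indexing="ij")
    total = counts.sum() or 1.0
    return pd.DataFrame(
        {
            "x_centre": xs.ravel(),
            "y_centre": ys.ravel(),
            "count": counts.ravel().astype(int),
            "density": counts.ravel() / total,
        }
    )


def violin_table(values: np.ndarray, n_bins: int = 40) -> pd.DataFrame:
    """1-D density table (bin centre, count, density) for violin exports."""
    values = np.asarray(values, float)
    counts, edges = np.histogram(values, bins=n_bins, density=False)
    centres = (edges[:-1] + edges[1:]) / 2
    total = counts.sum() or 1.0
    return pd.DataFrame(
        {"bin_centre": centres, "count": counts, "density": counts / total}
    )
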