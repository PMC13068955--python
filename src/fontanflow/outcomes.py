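"""Outcome analysis for time-varying cluster membership.

Because cluster assignment is made independently at every exam, a patient's
exposure changes over follow-up.  Risk is therefore modelled on
counting-process (start, stop] intervals: a time-varying Cox proportional-
hazards model (one indicator per non-reference cluster, adjusted for age,
sex, BSA, indexed aortic flow rate and ejection fraction) and Simon-Makuch
curves, the extension of Kaplan-Meier to time-varying group membership, with
curves truncated when fewer than ten individuals remain at risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "BSA", "ao_flow", "EF")
MIN_AT_RISK = 10


# --------------------------------------------------------------------------
# interval construction
# --------------------------------------------------------------------------

def build_intervals(assignments: pd.DataFrame, outcome: pd.DataFrame,
                    covariates=None) -> pd.DataFrame:
    """Counting-process rows from per-exam cluster assignments.

    ``assignments``: one row per exam with ``patient_id``, ``scan_time_yr``
    (years since the patient's first exam), ``cluster`` and any covariate
    columns.  ``outcome``: per patient ``time`` (years since first exam) and
    ``event``.  The cluster (and covariates) observed at each exam are
    carried forward to the next exam or to the event/censor time; the event
    flag sits only on the final interval.  Exams dated at or after the
    outcome time are rejected (reported in ``frame.attrs['rejected']``).
    """
    covariates = [c for c in (covariates or DEFAULT_COVARIATES)
                  if c in assignments.columns]
    out_by_pt = outcome.set_index("patient_id")
    rows, rejected = [], []
    for pid, grp in assignments.groupby("patient_id", sort=False):
        if pid not in out_by_pt.index:
            rejected.append((pid, "no outcome record"))
            continue
        t_end = float(out_by_pt.loc[pid, "time"])
        event = int(out_by_pt.loc[pid, "event"])
        grp = grp.sort_values("scan_time_yr")
        times = grp["scan_time_yr"].to_numpy(dtype=float)
        if times[0] != 0.0:
            times = times - times[0]
        keep = times < t_end
        if not keep[0]:
            rejected.append((pid, "event precedes first exam"))
            continue
        if (~keep).any():
            rejected.append((pid, "exam after event/censor time dropped"))
        grp = grp.iloc[keep]
        times = times[keep]
        stops = np.append(times[1:], t_end)
        for i, (_, exam) in enumerate(grp.iterrows()):
            if stops[i] <= times[i]:
                continue
            row = {"patient_id": pid, "start": times[i], "stop": stops[i],
                   "event": event if i == len(grp) - 1 else 0,
                   "cluster": exam["cluster"]}
            for c in covariates:
                row[c] = exam[c]
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["rejected"] = rejected
    return frame


# --------------------------------------------------------------------------
# time-varying Cox model
# --------------------------------------------------------------------------

@dataclass
class CoxTVResults:
    fitter: CoxTimeVaryingFitter
    reference: object
    clusters: list
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        s = self.fitter.summary
        rows = []
        for cl in self.clusters:
            name = f"cluster_{cl}"
            if name in s.index:
                r = s.loc[name]
                rows.append({"cluster": cl, "log_hr": r["coef"],
                             "hr": np.exp(r["coef"]), "se": r["se(coef)"],
                             "p": r["p"],
                             "hr_lower": np.exp(r["coef"] - 1.96 * r["se(coef)"]),
                             "hr_upper": np.exp(r["coef"] + 1.96 * r["se(coef)"])})
        self.table = pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Time-varying Cox PH (reference cluster {self.reference})"]
        for _, r in self.table.iterrows():
            lines.append(f"  cluster {r['cluster']}: HR {r['hr']:.2f} "
                         f"[{r['hr_lower']:.2f}, {r['hr_upper']:.2f}], "
                         f"p={r['p']:.3g}")
        return "\n".join(lines)


def _design(table: pd.DataFrame, reference, covariates) -> tuple:
    clusters = sorted(c for c in table["cluster"].unique() if c != reference)
    if not clusters:
        raise ValueError("need at least two clusters for a contrast")
    df = table[["patient_id", "start", "stop", "event"]].copy()
    for cl in clusters:
        df[f"cluster_{cl}"] = (table["cluster"] == cl).astype(float)
    for c in covariates:
        col = table[c]
        if col.dtype == object:
            col = pd.factorize(col)[0].astype(float)
        df[c] = np.asarray(col, dtype=float)
    return df, clusters


def cox_tv_fit(table: pd.DataFrame, reference=None,
               covariates=None) -> CoxTVResults:
    """Fit the time-varying Cox model with one cluster as reference.

    ``covariates`` defaults to whichever of age, sex, BSA, indexed aortic
    flow and EF are present in ``table``.  String covariates are factorized.
    """
    if table["event"].sum() < 1:
        raise ValueError("no events in table")
    if reference is None:
        reference = sorted(table["cluster"].unique())[0]
    covariates = [c for c in (covariates or DEFAULT_COVARIATES)
                  if c in table.columns]
    covariates = [c for c in covariates if table[c].nunique() > 1]
    df, clusters = _design(table, reference, covariates)
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(df, id_col="patient_id", event_col="event",
            start_col="start", stop_col="stop", show_progress=False)
    return CoxTVResults(fitter=ctv, reference=reference, clusters=clusters)


def hazard_ratio_grid(table: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Pairwise HRs using each cluster once as the reference group."""
    out = []
    for ref in sorted(table["cluster"].unique()):
        res = cox_tv_fit(table, reference=ref, covariates=covariates)
        t = res.table.copy()
        t.insert(0, "reference", ref)
        out.append(t)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# Simon-Makuch estimator
# --------------------------------------------------------------------------

def simon_makuch(table: pd.DataFrame, min_at_risk: int = MIN_AT_RISK) -> dict:
    """Survival step functions per cluster with time-varying membership.

    At every event time the at-risk set of each group is re-evaluated from
    the intervals covering that time (membership follows the current
    cluster).  A group's curve is truncated once its at-risk count drops
    below ``min_at_risk``.  Returns {group: DataFrame(time, at_risk,
    survival)}.
    """
    event_times = np.sort(table.loc[table["event"] == 1, "stop"].unique())
    groups = sorted(table["cluster"].unique())
    curves = {}
    for g in groups:
        rows = [{"time": 0.0, "at_risk": int(((table["cluster"] == g)
                                              & (table["start"] == 0)).sum()),
                 "survival": 1.0}]
        surv = 1.0
        truncated = rows[0]["at_risk"] < min_at_risk
        for t in event_times:
            if truncated:
                break
            in_g = table["cluster"] == g
            at_risk = in_g & (table["start"] < t) & (table["stop"] >= t)
            n = int(at_risk.sum())
            if n < min_at_risk:
                truncated = True
                break
            d = int((at_risk & (table["stop"] == t) & (table["event"] == 1)).sum())
            if d:
                surv *= 1.0 - d / n
            rows.append({"time": float(t), "at_risk": n, "survival": surv})
        curves[g] = pd.DataFrame(rows)
    return curves


def plot_simon_makuch(curves: dict, path=None, title="Simon-Makuch"):
    """Step plot of per-group survival curves; writes SVG when ``path`` set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for g, c in sorted(curves.items(), key=lambda kv: str(kv[0])):
        ax.step(c["time"], c["survival"], where="post", label=f"cluster {g}")
    ax.set_xlabel("years since first exam")
    ax.set_ylabel("event-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
        return None
    return fig


# --------------------------------------------------------------------------
# transitions and group comparison
# --------------------------------------------------------------------------

@dataclass
class TransitionSummary:
    n_multiscan: int
    n_transitions: int
    pct_same_first_last: float
    pct_same_consecutive: float

    def summary(self) -> str:
        return (f"{self.n_multiscan} patients with multiple scans, "
                f"{self.n_transitions} scan-to-scan transitions\n"
                f"  same cluster first-to-last: {self.pct_same_first_last:.0f}%\n"
                f"  same cluster between consecutive scans: "
                f"{self.pct_same_consecutive:.0f}%")


def transition_stats(assignments: pd.DataFrame) -> TransitionSummary:
    """Cluster-stability percentages among patients with >= 2 scans."""
    same_fl, n_multi = 0, 0
    same_cons, n_pairs = 0, 0
    for _, grp in assignments.groupby("patient_id", sort=False):
        seq = grp.sort_values("scan_time_yr")["cluster"].to_list()
        if len(seq) < 2:
            continue
        n_multi += 1
        same_fl += seq[0] == seq[-1]
        for a, b in zip(seq, seq[1:]):
            n_pairs += 1
            same_cons += a == b
    if n_multi == 0:
        raise ValueError("no patient has multiple scans")
    return TransitionSummary(
        n_multiscan=n_multi, n_transitions=n_pairs,
        pct_same_first_last=100.0 * same_fl / n_multi,
        pct_same_consecutive=100.0 * same_cons / n_pairs)


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Benjamini-Hochberg correction."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = ((counts ** 3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    pairs, pvals, zs = [], [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            pairs.append((a, b))
            zs.append(z)
            pvals.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return pd.DataFrame({"group_a": [p[0] for p in pairs],
                         "group_b": [p[1] for p in pairs],
                         "z": zs, "p": pvals, "p_adj": adj})


def group_compare(df: pd.DataFrame, group_col: str,
                  continuous=(), categorical=()) -> dict:
    """Kruskal-Wallis + Dunn(BH) for continuous and chi-square for
    categorical variables across clusters (synthetic-cohort utility).

    Groups with fewer than two members are excluded (noted in the report).
    """
    counts = df[group_col].value_counts()
    small = counts[counts < 2].index.tolist()
    data = df[~df[group_col].isin(small)]
    report = {"excluded_groups": small, "continuous": {}, "categorical": {}}
    for var in continuous:
        sub = data[[group_col, var]].dropna()
        samples = [g[var].to_numpy() for _, g in sub.groupby(group_col)]
        stat, p = stats.kruskal(*samples)
        report["continuous"][var] = {
            "kruskal_h": float(stat), "p": float(p),
            "dunn": dunn_posthoc(sub[var].to_numpy(), sub[group_col].to_numpy())}
    for var in categorical:
        tab = pd.crosstab(data[group_col], data[var])
        chi2, p, dof, _ = stats.chi2_contingency(tab)
        report["categorical"][var] = {"chi2": float(chi2), "p": float(p),
                                      "dof": int(dof)}
    return report
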