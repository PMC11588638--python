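"""Statistical comparisons and summary tables for typed repertoires.

Group comparisons use the two-tailed Mann-Whitney U test (exact permutation
enumeration for small pooled samples, tie-corrected normal approximation
otherwise), Pearson correlation with its t-based two-sided test, and a
paired t test for per-animal aggregates.  P-values are annotated with the
star convention::

    ns   P > 0.05
    *    0.01 <= P <= 0.05
    **   0.001 <= P < 0.01
    ***  0.0001 <= P < 0.001
    **** P < 0.0001

No multiple-testing correction is applied; tables report raw P-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

TYPE_ORDER = ("Y_C2", "F_C2", "F_C4", "N_V3", "N_V4")

EXACT_MWU_MAX_N = 20


def stars(p: float) -> str:
    """Significance stars for a P-value (total on [0, 1])."""
    if math.isnan(p):
        return "ns"
    if p > 0.05:
        return "ns"
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    if p >= 0.0001:
        return "***"
    return "****"


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, str]
    statistic: float
    p_value: float
    stars: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float], label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    For pooled sizes up to 20 the null distribution of U is enumerated
    exactly over all group assignments of the pooled observations (valid with
    ties); larger samples use the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty sample")
    u = _u_statistic(a, b)
    n = a.size + b.size
    if n <= EXACT_MWU_MAX_N:
        # ranks of the pooled sample are permutation-invariant, so U of any
        # reassignment is a subset rank sum; enumerate all of them
        ranks = sps.rankdata(np.concatenate([a, b]))
        offset = a.size * (a.size + 1) / 2.0
        n_le = n_ge = total = 0
        for combo in itertools.combinations(ranks, a.size):
            u_perm = sum(combo) - offset
            total += 1
            if u_perm <= u + 1e-9:
                n_le += 1
            if u_perm >= u - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return GroupComparison((label_a, label_b), float(u), p, stars(p))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided t-based P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t_test(
    values_a: Sequence[float], values_b: Sequence[float], label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Two-sided paired t test (per-animal aggregates are paired by animal).

    Degenerate cases: all differences zero -> t = 0, P = 1; constant nonzero
    differences (zero variance) -> infinite t, P = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("need at least two pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return GroupComparison((label_a, label_b), 0.0, 1.0, "ns")
        t = math.inf if diff[0] > 0 else -math.inf
        return GroupComparison((label_a, label_b), t, 0.0, stars(0.0))
    t, p = sps.ttest_rel(a, b)
    return GroupComparison((label_a, label_b), float(t), float(p), stars(float(p)))


def _mean_se(values: pd.Series) -> tuple[float, float]:
    v = values.dropna()
    if len(v) == 0:
        return math.nan, math.nan
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
    return float(v.mean()), se


# --------------------------------------------------------------------------
# repertoire tables

def summarize_by_type(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables for a typed repertoire.

    ``df`` needs columns: vhh_type, classical, cdr3_length, mismatches,
    mismatch_score, net_charge_CDR3, animal_id, age_group, hinge.

    Returns
    -------
    dict with keys
        ``classical_vs_nonclassical`` -- mean +- SE of CDR3 length, mismatch
        count and CDR3 net charge per group, with Mann-Whitney stars;
        ``type_percentages`` -- type share overall and per age group;
        ``hinge_usage`` -- mean per-animal 2B/2C percentage per type;
        ``mismatch_scores`` -- mean +- SE per type overall, per age group and
        per hinge.
    """
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    features = [c for c in ("cdr3_length", "mismatches", "net_charge_CDR3") if c in df]
    for label, group in (("Classical", df[df["classical"]]), ("Non-classical", df[~df["classical"]])):
        row: dict[str, object] = {
            "group": label,
            "percentage": 100.0 * len(group) / len(df) if len(df) else math.nan,
        }
        for feat in features:
            m, se = _mean_se(group[feat])
            row[f"{feat}_mean"] = m
            row[f"{feat}_se"] = se
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    for feat in features:
        a = df.loc[df["classical"], feat].dropna()
        b = df.loc[~df["classical"], feat].dropna()
        if len(a) and len(b):
            table[f"{feat}_stars"] = mann_whitney_u(a, b, "classical", "non-classical").stars
    tables["classical_vs_nonclassical"] = table

    pct = {"All": df["vhh_type"].value_counts(normalize=True) * 100}
    for age, group in df.groupby("age_group"):
        pct[f"Age {age}"] = group["vhh_type"].value_counts(normalize=True) * 100
    type_index = [t for t in (*TYPE_ORDER, "UNASSIGNED") if t in set(df["vhh_type"])]
    tables["type_percentages"] = (
        pd.DataFrame(pct).reindex(type_index).fillna(0.0).round(6)
    )

    if "hinge" in df:
        per_animal = (
            df.groupby(["vhh_type", "animal_id"])["hinge"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            * 100
        )
        tables["hinge_usage"] = (
            per_animal.groupby("vhh_type").mean().reindex(type_index).dropna(how="all")
        )

    if "mismatch_score" in df:
        rows = []
        for vhh_type in type_index:
            group = df[df["vhh_type"] == vhh_type]
            row = {"vhh_type": vhh_type}
            row["All_mean"], row["All_se"] = _mean_se(group["mismatch_score"])
            for age in ("3-4", "1-2", "0-1"):
                m, se = _mean_se(group.loc[group["age_group"] == age, "mismatch_score"])
                row[f"Age {age}_mean"], row[f"Age {age}_se"] = m, se
            for hinge in ("2B", "2C"):
                m, se = _mean_se(group.loc[group["hinge"] == hinge, "mismatch_score"])
                row[f"{hinge}_mean"], row[f"{hinge}_se"] = m, se
            rows.append(row)
        tables["mismatch_scores"] = pd.DataFrame(rows).set_index("vhh_type")
    return tables


# --------------------------------------------------------------------------
# interface tables

def summarize_interfaces(df: pd.DataFrame) -> dict[str, object]:
    """Interface statistics for typed complexes.

    ``df`` needs one row per complex with columns: vhh_type, paratope_kind,
    cdr3_length, bsa_epitope, bsa_paratope, contacts_CDR1 .. contacts_FR2,
    fr2_positions (iterable of contacted FR2 IMGT labels).

    Returns per-type contact-count summaries, the pairwise Pearson matrix of
    region contact counts per type, the FR2-involving fraction per type,
    paratope-kind comparisons of CDR3 length and interface size, a
    per-FR2-position usage profile, and the top-3 FR2 positions among
    FR2-involving complexes per type (ties broken toward the lower position).
    """
    out: dict[str, object] = {}
    regions = ["CDR1", "CDR2", "CDR3", "FR2"]
    type_index = [t for t in TYPE_ORDER if t in set(df["vhh_type"])]

    rows = []
    for vhh_type in type_index:
        group = df[df["vhh_type"] == vhh_type]
        row: dict[str, object] = {"vhh_type": vhh_type, "n": len(group)}
        for region in regions:
            m, se = _mean_se(group[f"contacts_{region}"])
            row[f"{region}_mean"], row[f"{region}_se"] = m, se
        rows.append(row)
    out["contact_counts"] = pd.DataFrame(rows).set_index("vhh_type")

    corr: dict[str, pd.DataFrame] = {}
    for vhh_type in type_index:
        group = df[df["vhh_type"] == vhh_type]
        mat = pd.DataFrame(index=regions, columns=regions, dtype=float)
        for r1, r2 in itertools.combinations_with_replacement(regions, 2):
            if r1 == r2:
                mat.loc[r1, r2] = 1.0
                continue
            x, y = group[f"contacts_{r1}"], group[f"contacts_{r2}"]
            try:
                r, _ = pearson_correlation(x, y)
            except ValidationError:
                r = math.nan
            mat.loc[r1, r2] = mat.loc[r2, r1] = r
        corr[vhh_type] = mat
    out["contact_correlations"] = corr

    frac = {
        t: 100.0 * (df.loc[df["vhh_type"] == t, "paratope_kind"] == "FR2_involving").mean()
        for t in type_index
    }
    out["fr2_involving_pct"] = pd.Series(frac, name="fr2_involving_pct")

    comparisons = {}
    fr2 = df[df["paratope_kind"] == "FR2_involving"]
    non = df[df["paratope_kind"] == "non_FR2"]
    for feat in ("cdr3_length", "bsa_epitope", "bsa_paratope"):
        if feat in df and len(fr2) and len(non):
            comparisons[feat] = mann_whitney_u(
                fr2[feat].dropna(), non[feat].dropna(), "FR2_involving", "non_FR2"
            )
    out["paratope_kind_comparisons"] = comparisons

    if "fr2_positions" in df:
        usage_rows = []
        top3_rows = []
        for vhh_type in type_index:
            group = df[(df["vhh_type"] == vhh_type) & (df["paratope_kind"] == "FR2_involving")]
            if len(group) == 0:
                continue
            counts: dict[str, int] = {}
            for positions in group["fr2_positions"]:
                for pos in positions:
                    counts[pos] = counts.get(pos, 0) + 1
            usage = {pos: 100.0 * c / len(group) for pos, c in counts.items()}
            for pos, pctv in usage.items():
                usage_rows.append({"vhh_type": vhh_type, "imgt_position": pos, "pct": pctv})
            ranked = sorted(usage.items(), key=lambda kv: (-kv[1], int(kv[0])))
            for rank, (pos, pctv) in enumerate(ranked[:3], start=1):
                top3_rows.append(
                    {"vhh_type": vhh_type, "rank": rank, "imgt_position": pos, "pct": pctv}
                )
        out["fr2_position_usage"] = pd.DataFrame(usage_rows)
        out["fr2_top3"] = pd.DataFrame(top3_rows)
        if not top3_rows:
            out["fr2_top3_notice"] = "no FR2-involving complexes in the dataset"
    return out


def interface_summary_frame(
    summaries: Sequence, types: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Flatten InterfaceSummary objects (plus optional type labels) to a table."""
    rows = []
    for s in summaries:
        row = {
            "complex_id": s.complex_id,
            "vhh_type": (types or {}).get(s.complex_id, "UNASSIGNED"),
            "epitope_size": len(s.epitope),
            "paratope_size": len(s.paratope),
            "paratope_kind": s.paratope_kind,
            "bsa_epitope": s.bsa_epitope,
            "bsa_paratope": s.bsa_paratope,
            "min_dist_42_cdr3": s.min_dist_42_cdr3,
            "fr2_positions": s.fr2_positions_contacted,
        }
        for region, count in s.contacts_by_region.items():
            row[f"contacts_{region}"] = count
        rows.append(row)
    return pd.DataFrame(rows)
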