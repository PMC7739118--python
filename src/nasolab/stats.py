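"""Reliability and validity statistics for panel ratings.

Two panels (professional and lay, five raters each in the study design)
score five 1-5 Likert parameters per case — scar length visibility, scar
width (vermilion continuity), height disparity at the vermilion border,
vertical (Y) asymmetry and depth (Z) asymmetry — on two occasions.
This module computes the composite scores, intra-rater reproducibility
(Wilcoxon signed-rank, Kendall tau-b), inter-panel agreement
(Kruskal-Wallis, Kendall tau-b) and the correlation between subjective
scores and the objective asymmetry / scar-area measurements.

Conventions (ordinal 1-5 data is tie-heavy, so they matter):

* Kendall correlation is tau-b (tie corrections in both margins).
* Wilcoxon drops zero differences (classic procedure) and notes it.
* Exact small-sample p-values are computed by enumeration — sign-flip
  distribution for Wilcoxon (handles ties in |d|), permutation for tau-b,
  group-label enumeration for Kruskal-Wallis; asymptotic tie-corrected
  approximations otherwise.
* No multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

SCORE_COLUMNS = ("scar_length", "scar_width", "vb_disparity", "asym_y", "asym_z")
COMPOSITE_COLUMNS = ("scar_composite", "asymmetry_composite", "total_score")
PARAMETERS = SCORE_COLUMNS + COMPOSITE_COLUMNS
PANELS = ("professional", "lay")

WILCOXON_EXACT_MAX_N = 25
KENDALL_EXACT_MAX_N = 8
KRUSKAL_EXACT_MAX_N = 10


@dataclass
class RatingRecord:
    """One rater-occasion-case row of five 1-5 Likert scores."""

    case: str
    rater: str
    panel: str
    occasion: int
    scar_length: int
    scar_width: int
    vb_disparity: int
    asym_y: int
    asym_z: int

    def __post_init__(self):
        if self.panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}, got {self.panel!r}")
        if self.occasion not in (1, 2):
            raise ValueError(f"occasion must be 1 or 2, got {self.occasion!r}")
        for name in SCORE_COLUMNS:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing score {name}")
            if not float(v).is_integer() or not 1 <= int(v) <= 5:
                raise ValueError(f"score {name}={v!r} is not an integer in [1, 5]")
            setattr(self, name, int(v))

    def scores(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in SCORE_COLUMNS}


@dataclass
class StatResult:
    """A (method, statistic, p) triple with sample size and caveat notes."""

    method: str
    statistic: float
    p: float
    n: int
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def composite_scores(record) -> tuple[int, int, int]:
    """(scar, asymmetry, total) composites of one record.

    scar = length + width; asymmetry = vermilion-border height disparity +
    vertical + depth asymmetry; total = sum of all five."""
    if isinstance(record, dict):
        record = RatingRecord(**record)
    s = record.scores()
    scar = s["scar_length"] + s["scar_width"]
    asym = s["vb_disparity"] + s["asym_y"] + s["asym_z"]
    return scar, asym, scar + asym


def _signed_rank_exact_p(weights: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by sign-flip
    enumeration, via the generating polynomial of the (doubled, hence
    integral even with average ranks) rank weights."""
    w2 = np.round(weights * 2).astype(np.int64)
    total = int(w2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for w in w2:
        shifted = np.zeros_like(poly)
        shifted[w:] = poly[: len(poly) - w]
        poly = poly + shifted
    poly /= poly.sum()
    obs = int(round(w_plus * 2))
    lo = poly[: obs + 1].sum()
    hi = poly[obs:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied |differences| get average ranks.
    Exact p by sign-flip enumeration for effective n <= 25, otherwise the
    tie- and continuity-corrected normal approximation.  If every
    difference is zero the statistic is undefined and p = 1 is returned
    with a note."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d samples, n >= 1")
    d = x - y
    notes = []
    nz = d != 0
    n_dropped = int((~nz).sum())
    if n_dropped:
        notes.append(f"{n_dropped} zero differences dropped")
    d = d[nz]
    n = len(d)
    if n == 0:
        return StatResult("wilcoxon_signed_rank", float("nan"), 1.0, 0,
                          notes + ["all-zero differences; test undefined"])
    ranks = sps.rankdata(np.abs(d))
    if len(np.unique(np.abs(d))) < n:
        notes.append("ties in |differences|; average ranks used")
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
        notes.append("exact sign-flip enumeration")
    else:
        res = sps.wilcoxon(x[nz], y[nz], zero_method="wilcox",
                           correction=True, method="approx")
        p = float(res.pvalue)
        notes.append("normal approximation with tie and continuity correction")
    return StatResult("wilcoxon_signed_rank", w_plus, p, n, notes)


def _tau_b_numerator(x: np.ndarray, y: np.ndarray) -> float:
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    return float((sx * sy)[np.triu_indices(len(x), k=1)].sum())


def kendall_tau_b(x, y) -> StatResult:
    """Kendall rank correlation tau-b with tie corrections in both margins.

    p is exact (permutation enumeration, valid under ties) for n <= 8,
    otherwise the tie-corrected normal approximation.  A fully tied margin
    leaves tau undefined and raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d samples, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("a margin is fully tied; tau-b is undefined")
    n = len(x)
    res = sps.kendalltau(x, y, variant="b")
    tau = float(res.statistic)
    notes = []
    if n <= KENDALL_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        iu = np.triu_indices(n, k=1)
        sx = np.sign(x[:, None] - x[None, :])[iu]
        yp = y[perms]
        syp = np.sign(yp[:, :, None] - yp[:, None, :])[:, iu[0], iu[1]]
        num = syp @ sx
        obs = abs(_tau_b_numerator(x, y))
        p = float(np.mean(np.abs(num) >= obs - 1e-9))
        notes.append("exact permutation enumeration")
    else:
        p = float(res.pvalue)
        notes.append("tie-corrected normal approximation")
    if len(np.unique(x)) < n or len(np.unique(y)) < n:
        notes.append("ties present; tau-b tie correction applied")
    return StatResult("kendall_tau_b", tau, p, n, notes)


def _kruskal_h(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offs = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for i, g in enumerate(groups):
        r = ranks[offs[i]:offs[i + 1]]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups, exact: bool | None = None) -> StatResult:
    """Kruskal-Wallis H test across >= 2 groups, with tie correction.

    p from the chi-square approximation (k-1 d.f.); with ``exact=True``
    (total n <= 10) an exact permutation p over all group labelings is
    computed instead.  All-identical data gives H = 0, p = 1 with a note."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    notes = []
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal_wallis", 0.0, 1.0, n,
                          ["all values identical; H = 0 by convention"])
    h = _kruskal_h(groups)
    if exact:
        if n > KRUSKAL_EXACT_MAX_N:
            raise ValueError(
                f"exact enumeration limited to total n <= {KRUSKAL_EXACT_MAX_N}"
            )
        sizes = [len(g) for g in groups]
        count = 0
        total = 0
        for labeling in _group_assignments(n, sizes):
            hh = _kruskal_h([pooled[list(ix)] for ix in labeling])
            total += 1
            if hh >= h - 1e-9:
                count += 1
        p = count / total
        notes.append("exact permutation enumeration")
    else:
        p = float(sps.chi2.sf(h, df=len(groups) - 1))
        notes.append("chi-square approximation")
    if len(np.unique(pooled)) < n:
        notes.append("ties present; tie-corrected H")
    return StatResult("kruskal_wallis", float(h), float(p), n, notes)


def _group_assignments(n: int, sizes: list[int]):
    """All distinct assignments of n indices into ordered groups of the
    given sizes."""
    def rec(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        first = remaining[0]
        # fix the smallest remaining index into the first slot of ... no:
        # groups are distinguishable (ordered), enumerate all combinations
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield [combo] + tail
        del first
    yield from rec(tuple(range(n)), sizes)


# ---------------------------------------------------------------------------
# rating tables


def read_ratings_csv(path) -> pd.DataFrame:
    """Read a ratings CSV with header
    case,rater,panel,occasion,scar_length,scar_width,vb_disparity,asym_y,asym_z
    validating every row and appending the composite columns."""
    df = pd.read_csv(path, dtype={"case": str, "rater": str, "panel": str})
    return validate_ratings(df)


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    required = ["case", "rater", "panel", "occasion", *SCORE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    df = df.copy()
    for _, row in df.iterrows():
        RatingRecord(
            case=str(row["case"]), rater=str(row["rater"]),
            panel=str(row["panel"]), occasion=int(row["occasion"]),
            **{c: row[c] for c in SCORE_COLUMNS},
        )
    dup = df.duplicated(subset=["case", "rater", "occasion"])
    if dup.any():
        raise ValueError("duplicate (case, rater, occasion) rows in ratings")
    df["scar_composite"] = df["scar_length"] + df["scar_width"]
    df["asymmetry_composite"] = df["vb_disparity"] + df["asym_y"] + df["asym_z"]
    df["total_score"] = df["scar_composite"] + df["asymmetry_composite"]
    return df


def intra_rater_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Intra-panel reproducibility between the two occasions.

    For each panel and each of the 8 parameters (5 raw + 3 composites),
    occasion-1 scores are paired with occasion-2 scores over the panel's
    pooled (rater, case) pairs; Wilcoxon signed-rank p and Kendall tau-b
    are reported — the layout of an intra-examiner reliability table."""
    ratings = validate_ratings(ratings) if "total_score" not in ratings else ratings
    rows = []
    for panel in PANELS:
        sub = ratings[ratings["panel"] == panel]
        if sub.empty:
            raise ValueError(f"panel {panel!r} missing from ratings")
        for occ in (1, 2):
            if not (sub["occasion"] == occ).any():
                raise ValueError(f"panel {panel!r} is missing occasion {occ}")
        o1 = sub[sub["occasion"] == 1].set_index(["rater", "case"]).sort_index()
        o2 = sub[sub["occasion"] == 2].set_index(["rater", "case"]).sort_index()
        common = o1.index.intersection(o2.index)
        for param in PARAMETERS:
            a = o1.loc[common, param].to_numpy(float)
            b = o2.loc[common, param].to_numpy(float)
            w = wilcoxon_signed_rank(a, b)
            try:
                tau = kendall_tau_b(a, b).statistic
            except ValueError:
                tau = float("nan")
            rows.append({"panel": panel, "parameter": param,
                         "wilcoxon_p": w.p, "kendall_tau": tau, "n": w.n})
    return pd.DataFrame(rows)


def inter_panel_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Inter-panel agreement per occasion.

    Kruskal-Wallis compares the pooled per-rater-case scores of the two
    panels; Kendall tau-b correlates the per-case panel means (panels have
    different raters, so pairing is only meaningful at case level)."""
    ratings = validate_ratings(ratings) if "total_score" not in ratings else ratings
    for panel in PANELS:
        if not (ratings["panel"] == panel).any():
            raise ValueError(f"panel {panel!r} missing from ratings")
    rows = []
    for occ in (1, 2):
        sub = ratings[ratings["occasion"] == occ]
        if sub.empty:
            raise ValueError(f"occasion {occ} missing from ratings")
        for param in PARAMETERS:
            groups = [sub[sub["panel"] == p][param].to_numpy(float)
                      for p in PANELS]
            kw = kruskal_wallis(groups)
            means = sub.pivot_table(index="case", columns="panel",
                                    values=param, aggfunc="mean")
            try:
                tau = kendall_tau_b(
                    means[PANELS[0]].to_numpy(), means[PANELS[1]].to_numpy()
                ).statistic
            except ValueError:
                tau = float("nan")
            rows.append({"occasion": occ, "parameter": param,
                         "kruskal_wallis_p": kw.p, "kendall_tau": tau,
                         "n": kw.n})
    return pd.DataFrame(rows)


def reliability_tables(ratings: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Both reliability tables: ``intra`` (per panel, between occasions)
    and ``inter`` (between panels, per occasion)."""
    ratings = validate_ratings(ratings)
    return {"intra": intra_rater_table(ratings),
            "inter": inter_panel_table(ratings)}


def subjective_objective_correlation(
    ratings: pd.DataFrame, measurements: pd.DataFrame
) -> pd.DataFrame:
    """Kendall tau-b between subjective composites and objective measures.

    ``measurements`` needs columns case, scar_area_mm2, mean_total_mm.
    Per panel: tau between the per-case mean scar composite and the scar
    surface area, and between the per-case mean asymmetry composite and the
    mean total disparity.  Occasions are pooled into the case mean."""
    ratings = validate_ratings(ratings)
    for col in ("case", "scar_area_mm2", "mean_total_mm"):
        if col not in measurements.columns:
            raise ValueError(f"measurements table missing column {col!r}")
    meas = measurements.set_index(measurements["case"].astype(str))
    rated_cases = set(ratings["case"].astype(str))
    missing = sorted(rated_cases - set(meas.index))
    if missing:
        raise ValueError(f"cases missing objective measurements: {missing}")
    rows = []
    for panel in PANELS:
        sub = ratings[ratings["panel"] == panel]
        if sub.empty:
            continue
        means = sub.groupby(sub["case"].astype(str))[
            ["scar_composite", "asymmetry_composite"]
        ].mean()
        cases = means.index
        for subj, obj in (("scar_composite", "scar_area_mm2"),
                          ("asymmetry_composite", "mean_total_mm")):
            try:
                r = kendall_tau_b(
                    means[subj].to_numpy(),
                    meas.loc[cases, obj].to_numpy(float))
                tau, p, n = r.statistic, r.p, r.n
            except ValueError:  # a fully tied margin leaves tau undefined
                tau, p, n = float("nan"), float("nan"), len(cases)
            rows.append({"panel": panel, "subjective": subj, "objective": obj,
                         "kendall_tau": tau, "p": p, "n": n})
    return pd.DataFrame(rows)


def simulate_ratings(
    measurements: pd.DataFrame,
    n_raters: int = 5,
    seed: int = 0,
    rater_sd: float = 0.7,
    repeat_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate two-panel Likert ratings driven by the objective measures.

    Severity anchors map each case's scar area and asymmetry onto the 1-5
    scale (higher = more severe); rater noise and a second-occasion
    re-rating noise are added and scores are rounded and clamped.  Used to
    exercise the reliability tables when no human panel data exist."""
    for col in ("case", "scar_area_mm2", "mean_total_mm"):
        if col not in measurements.columns:
            raise ValueError(f"measurements table missing column {col!r}")
    rng = np.random.default_rng(seed)

    def to_scale(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        lo, hi = v.min(), v.max()
        if hi - lo < 1e-12:
            return np.full_like(v, 3.0)
        return 1.0 + 4.0 * (v - lo) / (hi - lo)

    scar_level = to_scale(measurements["scar_area_mm2"])
    asym_level = to_scale(measurements["mean_total_mm"])
    rows = []
    for panel in PANELS:
        for r in range(n_raters):
            bias = rng.normal(0, 0.3)
            for occ in (1, 2):
                for i, case in enumerate(measurements["case"].astype(str)):
                    base = {
                        "scar_length": scar_level[i],
                        "scar_width": scar_level[i],
                        "vb_disparity": asym_level[i],
                        "asym_y": asym_level[i],
                        "asym_z": asym_level[i],
                    }
                    row = {"case": case, "rater": f"{panel[:4]}{r}",
                           "panel": panel, "occasion": occ}
                    for k, v in base.items():
                        noise = rng.normal(0, rater_sd)
                        if occ == 2:
                            noise += rng.normal(0, repeat_sd)
                        row[k] = int(np.clip(round(v + bias + noise), 1, 5))
                    rows.append(row)
    return validate_ratings(pd.DataFrame(rows))
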