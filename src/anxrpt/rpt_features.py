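"""Relative-preference feature extraction from picture ratings.

Relative Preference Theory (RPT) summarizes a participant's reward/aversion
judgments from a short picture-rating task: 48 pictures in 6 categories rated
on an integer scale from -3 (dislike very much) to +3 (like very much), 0
being neutral.

Per category the ratings are split by sign (zeros belong to neither set) and
each signed set is reduced to a triple (K, sigma, H):

* K      - the signed mean rating,
* sigma  - the (population) variance of the signed ratings,
* H      - the Shannon entropy, in bits, of the distribution of rating
           magnitudes |r| in {1, 2, 3} within the set.

Three curve families are then fit per participant across the six categories:

* value function    K = f(H) per limb (concave logarithmic or power law),
* limit function    sigma = alpha*K^2 + beta*K + gamma (one concave quadratic
                    across both signs; Markowitz-style risk-vs-value curve),
* tradeoff function polar summary of the per-category (H+, H-) points.

Fifteen judgment variables are read off these curves: LA, RA, LR, Ante and
Insurance from the value function; Peak PR, Peak NR, Reward TP, Aversion TP,
Total RR and Total AR from the limit function; RA tradeoff, Tradeoff range,
RA consistency and Consistency range from the tradeoff function.

Fit failures never raise: they mark the participant's profile incomplete, and
incomplete profiles are dropped by :func:`apply_rating_exclusions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

JUDGMENT_VARIABLES: tuple[str, ...] = (
    "LA", "RA", "LR", "Ante", "Insurance",
    "PeakPR", "PeakNR", "RewardTP", "AversionTP", "TotalRR", "TotalAR",
    "RATradeoff", "TradeoffRange", "RAConsistency", "ConsistencyRange",
)

N_CATEGORIES = 6
PICTURES_PER_CATEGORY = 8
MAX_ENTROPY_BITS = math.log2(3.0)


# ---------------------------------------------------------------------------
# signed summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedSummary:
    """(K, sigma, H) triple for one participant x category x sign."""

    category: int
    sign: str  # '+' or '-'
    k: float
    sigma: float
    h: float
    n: int


def shannon_entropy_bits(magnitudes: Sequence[int]) -> float:
    """Entropy in bits of the empirical distribution of |rating| in {1,2,3}.

    Uses the convention 0*log(0) = 0, so degenerate sets have H = 0.
    """
    mags = np.asarray(magnitudes, dtype=int)
    if mags.size == 0:
        return float("nan")
    counts = np.bincount(mags, minlength=4)[1:4]
    p = counts[counts > 0] / mags.size
    return float(-(p * np.log2(p)).sum())


def signed_summary(ratings: Sequence[int], sign: str, category: int = 0,
                   *, sample_variance: bool = False) -> SignedSummary | None:
    """Summarize the positive or negative ratings of one category.

    Returns None when the signed set is empty (an undefined tuple, flagged
    rather than fabricated). Population variance is the default; a sample
    variance convention is available behind the flag.
    """
    r = np.asarray(ratings, dtype=int)
    subset = r[r > 0] if sign == "+" else r[r < 0]
    if subset.size == 0:
        return None
    ddof = 1 if (sample_variance and subset.size > 1) else 0
    return SignedSummary(
        category=category,
        sign=sign,
        k=float(subset.mean()),
        sigma=float(subset.var(ddof=ddof)),
        h=shannon_entropy_bits(np.abs(subset)),
        n=int(subset.size),
    )


def summarize_ratings(ratings: pd.DataFrame, *, sample_variance: bool = False
                      ) -> tuple[list[SignedSummary], dict[str, float]]:
    """Per-category signed (K, sigma, H) tuples plus cross-category means.

    ``ratings`` holds one participant's long-format table with columns
    ``category`` and ``rating`` (48 rows expected: 6 categories x 8 pictures).
    Cross-category means average only over categories with a defined tuple.
    """
    if len(ratings) != N_CATEGORIES * PICTURES_PER_CATEGORY:
        raise ValueError(f"expected 48 ratings, got {len(ratings)}")
    summaries: list[SignedSummary] = []
    for cat, grp in ratings.groupby("category"):
        vals = grp["rating"].to_numpy()
        for sign in ("+", "-"):
            s = signed_summary(vals, sign, int(cat), sample_variance=sample_variance)
            if s is not None:
                summaries.append(s)
    means: dict[str, float] = {}
    for sign in ("+", "-"):
        sub = [s for s in summaries if s.sign == sign]
        if sub:
            means[f"mean_k{sign}"] = float(np.mean([s.k for s in sub]))
            means[f"mean_sigma{sign}"] = float(np.mean([s.sigma for s in sub]))
            means[f"mean_h{sign}"] = float(np.mean([s.h for s in sub]))
    return summaries, means


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

@dataclass
class CurveFit:
    """A fitted curve with ordinary goodness-of-fit diagnostics."""

    family: str  # 'log', 'power', 'quadratic', 'radial'
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    f_stat: float
    n_points: int
    ok: bool = True
    notes: list[str] = field(default_factory=list)


def _gof(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float, float]:
    """R^2, adjusted R^2 and overall F for a least-squares fit."""
    n = y.size
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    p = n_params - 1  # predictors excluding intercept
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    dof = n - n_params
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
    if dof > 0 and (1.0 - r2) > 1e-15:
        f = (r2 / p) / ((1.0 - r2) / dof)
    else:
        f = float("inf") if r2 > 0 else float("nan")
    return r2, adj, f


def _fit_log_limb(h: np.ndarray, k: np.ndarray) -> CurveFit:
    """K = a*ln(H) + b by ordinary least squares."""
    x = np.log(h)
    a, b = np.polyfit(x, k, 1)
    r2, adj, f = _gof(k, a * x + b, 2)
    return CurveFit("log", {"a": float(a), "b": float(b)}, r2, adj, f, h.size)


def _fit_power_limb(h: np.ndarray, k: np.ndarray) -> CurveFit:
    """K = b*H^a by least squares (nonlinear; log-log linearization as start)."""
    sign = 1.0 if np.median(k) >= 0 else -1.0
    absk = np.abs(k)
    with np.errstate(divide="ignore"):
        mask = absk > 0
        if mask.sum() >= 2:
            a0, logb0 = np.polyfit(np.log(h[mask]), np.log(absk[mask]), 1)
            b0 = sign * math.exp(logb0)
        else:
            a0, b0 = 1.0, sign
    try:
        (a, b), _ = optimize.curve_fit(
            lambda x, a, b: b * np.power(x, a), h, k, p0=[a0, b0], maxfev=5000)
        fit = CurveFit("power", {"a": float(a), "b": float(b)},
                       *_gof(k, b * np.power(h, a), 2), h.size)
    except (RuntimeError, ValueError):
        fit = CurveFit("power", {"a": float(a0), "b": float(b0)},
                       float("nan"), -np.inf, float("nan"), h.size, ok=False,
                       notes=["power fit did not converge"])
    return fit


def fit_value_function(points: Sequence[tuple[float, float]], sign: str) -> CurveFit | None:
    """Fit one value-function limb K = f(H) from per-category (H, K) points.

    Both the logarithmic (K = a*ln H + b) and power (K = b*H^a) families are
    fit; the one with the higher adjusted R^2 is retained (ties favour log).
    Points with H = 0 are excluded (ln undefined) and recorded; fewer than 3
    usable points leaves the limb undefined.

    The positive limb is expected to rise with entropy (a > 0) and the
    negative limb to fall (a < 0); violations are flagged, not fabricated.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return None
    h, k = pts[:, 0], pts[:, 1]
    usable = h > 0
    n_dropped = int((~usable).sum())
    h, k = h[usable], k[usable]
    if h.size < 3:
        return None
    log_fit = _fit_log_limb(h, k)
    pow_fit = _fit_power_limb(h, k)
    fit = pow_fit if (pow_fit.ok and pow_fit.adj_r2 > log_fit.adj_r2) else log_fit
    if n_dropped:
        fit.notes.append(f"{n_dropped} zero-entropy point(s) excluded")
    a = fit.coefficients["a"]
    slope_ok = a > 0 if sign == "+" else a < 0
    if not slope_ok:
        fit.ok = False
        fit.notes.append(f"unexpected {sign} limb slope a={a:.3g}")
    return fit


def extract_value_features(pos: CurveFit | None, neg: CurveFit | None,
                           mean_h_pos: float, mean_h_neg: float) -> dict[str, float]:
    """LA, RA, LR, Ante, Insurance from the two value-function limbs.

    * LA (loss aversion)  = |a-| / a+  - negative-to-positive limb steepness.
    * RA (risk aversion)  = curvature magnitude of the positive limb at the
      participant's mean H+ (|d2K/dH2| evaluated at mean H+).
    * LR (loss resilience) = same curvature magnitude on the negative limb at
      mean H-.
    * Ante       = positive limb value at unit entropy (H = 1).
    * Insurance  = magnitude of the negative limb value at unit entropy.

    Returns NaN for features whose prerequisites are undefined.
    """
    out = {k: float("nan") for k in ("LA", "RA", "LR", "Ante", "Insurance")}
    if pos is not None:
        out["RA"] = _limb_curvature(pos, mean_h_pos)
        out["Ante"] = _limb_value_at(pos, 1.0)
    if neg is not None:
        out["LR"] = _limb_curvature(neg, mean_h_neg)
        out["Insurance"] = abs(_limb_value_at(neg, 1.0))
    if pos is not None and neg is not None and _limb_slope(pos) > 0:
        out["LA"] = abs(_limb_slope(neg)) / _limb_slope(pos)
    return out


def _limb_value_at(fit: CurveFit, h: float) -> float:
    a, b = fit.coefficients["a"], fit.coefficients["b"]
    if fit.family == "log":
        return a * math.log(h) + b
    return b * h ** a


def _limb_slope(fit: CurveFit) -> float:
    """Signed dK/dH at H = 1 — the limb's characteristic steepness."""
    a, b = fit.coefficients["a"], fit.coefficients["b"]
    if fit.family == "log":
        return a
    return a * b


def _limb_curvature(fit: CurveFit, h: float) -> float:
    """|d2K/dH2| evaluated at entropy h."""
    a, b = fit.coefficients["a"], fit.coefficients["b"]
    if h <= 0 or not np.isfinite(h):
        return float("nan")
    if fit.family == "log":
        return abs(a) / h ** 2
    return abs(b * a * (a - 1.0) * h ** (a - 2.0))


def fit_limit_function(points: Sequence[tuple[float, float]]) -> CurveFit | None:
    """Fit the concave quadratic sigma = alpha*K^2 + beta*K + gamma.

    ``points`` are the per-category (K, sigma) pairs from both signs, fit
    jointly over the signed K axis. Concavity (alpha < 0) and real roots
    straddling zero are required downstream; violations only flag the fit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        return None
    k, sigma = pts[:, 0], pts[:, 1]
    if np.ptp(k) == 0:
        return None
    alpha, beta, gamma = np.polyfit(k, sigma, 2)
    yhat = alpha * k ** 2 + beta * k + gamma
    r2, adj, f = _gof(sigma, yhat, 3)
    fit = CurveFit("quadratic",
                   {"alpha": float(alpha), "beta": float(beta), "gamma": float(gamma)},
                   r2, adj, f, k.size)
    if alpha >= 0:
        fit.ok = False
        fit.notes.append(f"non-concave quadratic (alpha={alpha:.3g})")
    return fit


def extract_limit_features(fit: CurveFit | None) -> dict[str, float]:
    """Peak PR/NR, Reward/Aversion tipping points, Total RR/AR.

    Requires a concave fit with real roots r- < 0 < r+. The tipping points
    are the roots; the peaks are the maxima of the fitted curve over the
    positive (approach) and negative (avoidance) half-intervals, with the
    open endpoint at K = 0 evaluated as sigma(0); the totals are the areas
    under the curve between zero and each root.
    """
    keys = ("PeakPR", "PeakNR", "RewardTP", "AversionTP", "TotalRR", "TotalAR")
    out = {k: float("nan") for k in keys}
    if fit is None or not fit.ok:
        return out
    alpha = fit.coefficients["alpha"]
    beta = fit.coefficients["beta"]
    gamma = fit.coefficients["gamma"]
    disc = beta ** 2 - 4 * alpha * gamma
    if alpha >= 0 or disc <= 0:
        return out
    sq = math.sqrt(disc)
    roots = sorted(((-beta - sq) / (2 * alpha), (-beta + sq) / (2 * alpha)))
    r_neg, r_pos = roots
    if not (r_neg < 0 < r_pos):
        return out

    def sigma_at(x: float) -> float:
        return alpha * x ** 2 + beta * x + gamma

    vertex = -beta / (2 * alpha)
    out["RewardTP"] = r_pos
    out["AversionTP"] = abs(r_neg)
    out["PeakPR"] = sigma_at(vertex) if vertex > 0 else sigma_at(0.0)
    out["PeakNR"] = sigma_at(vertex) if vertex < 0 else sigma_at(0.0)

    def integral(x: float) -> float:
        return alpha * x ** 3 / 3 + beta * x ** 2 / 2 + gamma * x

    out["TotalRR"] = integral(r_pos) - integral(0.0)
    out["TotalAR"] = abs(integral(0.0) - integral(r_neg))
    return out


def fit_tradeoff_function(points: Sequence[tuple[float, float]]) -> CurveFit | None:
    """Polar summary of the per-category (H+, H-) points.

    Each category maps to r = sqrt(H+^2 + H-^2) and theta = atan2(H-, H+),
    with theta in [0, pi/2] for non-negative entropies. Fewer than 2 valid
    points leaves the tradeoff undefined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return None
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.shape[0] < 2:
        return None
    hp, hn = pts[:, 0], pts[:, 1]
    r = np.hypot(hp, hn)
    theta = np.arctan2(hn, hp)
    coeffs = {"mean_r": float(r.mean()), "mean_theta": float(theta.mean()),
              "spread_r": float(np.ptp(r)), "spread_theta": float(np.ptp(theta))}
    fit = CurveFit("radial", coeffs, float("nan"), float("nan"), float("nan"), pts.shape[0])
    fit.points = list(zip(r.tolist(), theta.tolist()))  # type: ignore[attr-defined]
    return fit


def extract_tradeoff_features(fit: CurveFit | None) -> dict[str, float]:
    """RA tradeoff, Tradeoff range, RA consistency, Consistency range.

    The mean angle is the average bias of information toward approach versus
    avoidance; the angular range is the breadth of that bias across
    categories; the mean radius places the participant on the
    conflict-vs-indifference continuum; the radial range is its breadth.
    """
    keys = ("RATradeoff", "TradeoffRange", "RAConsistency", "ConsistencyRange")
    if fit is None:
        return {k: float("nan") for k in keys}
    c = fit.coefficients
    return {"RATradeoff": c["mean_theta"], "TradeoffRange": c["spread_theta"],
            "RAConsistency": c["mean_r"], "ConsistencyRange": c["spread_r"]}


# ---------------------------------------------------------------------------
# per-participant profiles
# ---------------------------------------------------------------------------

@dataclass
class JudgmentProfile:
    """The 15 judgment variables plus fit diagnostics for one participant."""

    participant_id: object
    features: dict[str, float]
    value_fit_pos: CurveFit | None
    value_fit_neg: CurveFit | None
    limit_fit: CurveFit | None
    tradeoff_fit: CurveFit | None

    @property
    def complete(self) -> bool:
        return all(np.isfinite(self.features.get(k, float("nan")))
                   for k in JUDGMENT_VARIABLES)


def compute_profile(participant_id: object, ratings: pd.DataFrame,
                    *, sample_variance: bool = False) -> JudgmentProfile:
    """Run the full RPT extraction for one participant's 48 ratings."""
    summaries, means = summarize_ratings(ratings, sample_variance=sample_variance)
    by_cat: dict[int, dict[str, SignedSummary]] = {}
    for s in summaries:
        by_cat.setdefault(s.category, {})[s.sign] = s

    pos_pts = [(s.h, s.k) for s in summaries if s.sign == "+"]
    neg_pts = [(s.h, s.k) for s in summaries if s.sign == "-"]
    pos_fit = fit_value_function(pos_pts, "+") if len(pos_pts) >= 3 else None
    neg_fit = fit_value_function(neg_pts, "-") if len(neg_pts) >= 3 else None
    # slope-sign violations are flagged on the fit, not nulled; only an
    # unusable positive slope leaves LA undefined (handled in extraction)
    features = extract_value_features(
        pos_fit, neg_fit,
        means.get("mean_h+", float("nan")), means.get("mean_h-", float("nan")))

    limit_pts = [(s.k, s.sigma) for s in summaries]
    limit_fit = fit_limit_function(limit_pts)
    features.update(extract_limit_features(limit_fit))

    trade_pts = [(cat["+"].h, cat["-"].h) for cat in by_cat.values()
                 if "+" in cat and "-" in cat]
    trade_fit = fit_tradeoff_function(trade_pts)
    features.update(extract_tradeoff_features(trade_fit))

    return JudgmentProfile(participant_id, features, pos_fit, neg_fit,
                           limit_fit, trade_fit)


def compute_profiles(ratings: pd.DataFrame, *, sample_variance: bool = False
                     ) -> pd.DataFrame:
    """Profiles for a long-format ratings table (all participants).

    Returns a DataFrame indexed by participant id with the 15 judgment
    variables, per-curve R^2 diagnostics and a ``complete`` flag.
    """
    rows = []
    for pid, grp in ratings.groupby("participant_id", sort=False):
        prof = compute_profile(pid, grp, sample_variance=sample_variance)
        row: dict[str, object] = {"participant_id": pid, **prof.features,
                                  "complete": prof.complete}
        for name, fit in (("value_pos", prof.value_fit_pos),
                          ("value_neg", prof.value_fit_neg),
                          ("limit", prof.limit_fit)):
            row[f"{name}_family"] = fit.family if fit else None
            row[f"{name}_r2"] = fit.r2 if fit else float("nan")
            row[f"{name}_adj_r2"] = fit.adj_r2 if fit else float("nan")
            row[f"{name}_f"] = fit.f_stat if fit else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


# ---------------------------------------------------------------------------
# rating-based exclusions
# ---------------------------------------------------------------------------

def apply_rating_exclusions(ratings: pd.DataFrame, profiles: pd.DataFrame,
                            *, mad_multiplier: float = 5.0):
    """Exclude low-variance raters, incomplete profiles and extreme outliers.

    * minimal variance: the participant's 48 ratings span at most one point
      (max - min <= 1);
    * incomplete: any of the 15 judgment variables undefined;
    * extreme outlier: |value - median| > ``mad_multiplier`` * MAD on any
      judgment variable (median/MAD taken over complete profiles).

    Returns a :class:`~anxrpt.survey_scores.FilterReport`.
    """
    from .survey_scores import FilterReport

    triggered: dict[object, list[str]] = {}

    def flag(pid: object, rule: str) -> None:
        triggered.setdefault(pid, []).append(rule)

    spans = ratings.groupby("participant_id")["rating"].agg(lambda v: v.max() - v.min())
    for pid, span in spans.items():
        if span <= 1:
            flag(pid, "minimal_rating_variance")

    for pid, row in profiles.iterrows():
        if not bool(row.get("complete", False)):
            flag(pid, "incomplete_profile")

    complete = profiles[profiles["complete"].astype(bool)]
    if len(complete):
        feats = complete[list(JUDGMENT_VARIABLES)]
        med = feats.median()
        mad = (feats - med).abs().median()
        for pid, row in feats.iterrows():
            dev = (row - med).abs()
            # a zero-MAD feature only flags genuinely deviant values
            over = dev > mad_multiplier * mad.where(mad > 0, dev.abs().max() + 1)
            if over.any():
                flag(pid, "extreme_outlier")

    all_ids = list(profiles.index)
    retained = [pid for pid in all_ids if pid not in triggered]
    counts: dict[str, int] = {}
    for rules in triggered.values():
        for r in rules:
            counts[r] = counts.get(r, 0) + 1
    return FilterReport(triggered=triggered, rule_counts=counts, retained_ids=retained)
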