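"""Posterior summaries, significance flags and odds-ratio reporting.

Summaries follow the publication's table layout: posterior mean, SD and a
95% credible interval per coefficient, a star for parameters whose interval
excludes zero (sign probability above 95%) and a dagger for "moderate"
effects — operationalised here as a sign probability in a configurable band
(default [0.90, 0.975)) while the interval still contains zero.

Because the mortality submodels code death = 1, survival odds ratios are the
exponentiated *negated* coefficients; :func:`odds_ratio_summary` makes the
direction explicit so the transform can never be applied silently the wrong
way round.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .blocks import BLOCKS, split_param_name
from .errors import ConfigurationError

SUMMARY_COLUMNS = ("parameter", "block", "term", "mean", "sd", "lo", "hi",
                   "interval_kind", "p_sign", "flag")

#: publication table block grouping, in print order
TABLE1_BLOCK_ORDER = (
    ("a", ("g1_surv_24h", "g1_surv_larval", "g1_surv_pupal", "g1_surv_adult")),
    ("b", ("g1_devtime", "g1_mass_emergence", "g1_mass_day10")),
    ("c", ("g2_surv_24h", "g2_surv_larval", "g2_surv_pupal", "g2_surv_adult")),
    ("d", ("g2_devtime", "g2_mass_emergence", "g2_mass_day7", "g2_mass_day14")),
    ("e", ("g2_lipid", "g2_water", "g2_drymass")),
)


@dataclass
class PosteriorSummary:
    """One parameter's posterior location, spread, interval and flags."""

    parameter: str
    mean: float
    sd: float
    lo: float
    hi: float
    interval_kind: str = "equal_tail"
    p_sign: float = float("nan")
    flag: str = "none"


def hpd_interval(sample, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``level`` of the draws.

    Implements the highest-posterior-density interval of a sample: the
    narrowest window of ``ceil(level * n)`` order statistics.  Requires at
    least 50 draws; an all-equal sample returns the degenerate interval
    ``(c, c)``.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 50:
        raise ValueError(f"hpd_interval requires at least 50 draws (got {n})")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m = int(np.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def equal_tail_interval(sample, level: float = 0.95) -> tuple[float, float]:
    """Quantile-based credible interval (the table's 2.5%/97.5% columns)."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(sample, dtype=float), [a, 1.0 - a])
    return float(lo), float(hi)


def _flag(lo: float, hi: float, p_sign: float, band) -> str:
    if not lo <= 0.0 <= hi:
        return "star"
    p = max(p_sign, 1.0 - p_sign)
    if band[0] <= p < band[1]:
        return "dagger"
    return "none"


def summarize(draws, interval_kind: str = "equal_tail", level: float = 0.95,
              dagger_band: tuple[float, float] = (0.90, 0.975)) -> pd.DataFrame:
    """Per-parameter posterior mean, SD, 95% interval, sign probability, flag.

    ``draws`` is a :class:`~sublethal.mcmc.PosteriorDraws` or any mapping /
    DataFrame of named draw vectors.  ``interval_kind`` selects equal-tailed
    quantiles (the published table's columns) or the HPD ("shortest
    interval") definition.  Flags: ``star`` when the interval excludes 0,
    ``dagger`` when the sign probability falls inside ``dagger_band`` while
    the interval still contains 0.
    """
    if interval_kind not in ("equal_tail", "hpd"):
        raise ConfigurationError(f"unknown interval_kind {interval_kind!r}")
    if hasattr(draws, "to_frame") and hasattr(draws, "names"):
        frame = draws.to_frame()
    elif isinstance(draws, pd.DataFrame):
        frame = draws
    else:
        frame = pd.DataFrame(dict(draws))

    rows = []
    for name in frame.columns:
        x = frame[name].to_numpy(dtype=float)
        if interval_kind == "hpd":
            lo, hi = hpd_interval(x) if x.std() > 0 else (float(x[0]), float(x[0]))
        else:
            lo, hi = equal_tail_interval(x, level)
        p_sign = float((x > 0).mean())
        try:
            block, term = split_param_name(name)
        except ValueError:
            block, term = "", name
        rows.append({
            "parameter": name, "block": block, "term": term,
            "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
            "lo": lo, "hi": hi, "interval_kind": interval_kind,
            "p_sign": p_sign, "flag": _flag(lo, hi, p_sign, dagger_band),
        })
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def summaries_as_objects(summary: pd.DataFrame) -> dict[str, PosteriorSummary]:
    """Summary table as a mapping of :class:`PosteriorSummary` objects."""
    return {r["parameter"]: PosteriorSummary(
        r["parameter"], r["mean"], r["sd"], r["lo"], r["hi"],
        r["interval_kind"], r["p_sign"], r["flag"])
        for _, r in summary.iterrows()}


@dataclass
class OddsRatioReport:
    """Odds ratio, its 95% interval and the probability it exceeds 1."""

    point: float
    lo: float | None = None
    hi: float | None = None
    p_greater_1: float | None = None
    direction: str = "survival"


def odds_ratio_summary(coefficient, direction: str,
                       interval: tuple[float, float] | None = None,
                       ndigits: int | None = None) -> OddsRatioReport:
    """Odds-ratio transform of a death-logit coefficient.

    ``direction='survival'`` reports ``exp(-x)`` (with interval endpoints
    swapped so ``lo < hi``); ``direction='death'`` reports ``exp(x)``.  The
    direction must be stated by the caller — it is never inferred.
    ``coefficient`` may be a point value or a vector of posterior draws; with
    draws, the point is the transform of the posterior mean, the interval the
    transform of the equal-tailed interval, and ``P(OR > 1)`` the fraction of
    draws on the favourable side.
    """
    if direction not in ("survival", "death"):
        raise ConfigurationError("direction must be 'survival' or 'death'")
    sign = -1.0 if direction == "survival" else 1.0
    x = np.asarray(coefficient, dtype=float)

    p_gt_1 = None
    if x.ndim and x.size > 1:
        if interval is None:
            interval = equal_tail_interval(x)
        p_gt_1 = float((sign * x > 0).mean())
        point_coef = float(x.mean())
    else:
        point_coef = float(x)

    point = float(np.exp(sign * point_coef))
    lo = hi = None
    if interval is not None:
        a, b = np.exp(sign * interval[0]), np.exp(sign * interval[1])
        lo, hi = (min(a, b), max(a, b))
    if ndigits is not None:
        point = round(point, ndigits)
        lo = None if lo is None else round(lo, ndigits)
        hi = None if hi is None else round(hi, ndigits)
    return OddsRatioReport(point, lo, hi, p_gt_1, direction)


def render_table1(summary: pd.DataFrame, blocks=None) -> pd.DataFrame:
    """Arrange summaries in the publication's block and row order.

    Returns the machine-readable variant (a DataFrame ordered like the
    printed table, with a ``table_block`` letter column); pass it to
    :func:`format_table1` for the human-readable text.  Raises
    :class:`ConfigurationError` when a requested block has no summaries.
    """
    order = []
    if blocks is None:
        blocks = [b for _, group in TABLE1_BLOCK_ORDER for b in group
                  if b in set(summary["block"])]
    available = set(summary["block"])
    for b in blocks:
        if b not in available:
            raise ConfigurationError(f"no summaries for block {b!r}")
    letter = {b: let for let, group in TABLE1_BLOCK_ORDER for b in group}
    for b in blocks:
        sub = summary[summary["block"] == b]
        covs = BLOCKS[b].covariates if b in BLOCKS else tuple(sub["term"])
        terms = [t for t in covs if t in set(sub["term"])]
        terms += [t for t in sub["term"] if t not in terms]
        for t in terms:
            row = sub[sub["term"] == t].iloc[0].to_dict()
            row["table_block"] = letter.get(b, "")
            order.append(row)
    cols = ["table_block"] + list(SUMMARY_COLUMNS)
    return pd.DataFrame(order)[cols]


def format_table1(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`render_table1` output."""
    marks = {"star": "*", "dagger": "†", "none": ""}
    lines = [f"{'parameter':40s} {'mean':>9s} {'sd':>8s} {'2.5%':>9s} "
             f"{'97.5%':>9s}"]
    current = None
    for _, r in table.iterrows():
        if r["block"] != current:
            current = r["block"]
            lines.append(f"-- ({r['table_block']}) {current}")
        lines.append(
            f"{r['term']:40s} {r['mean']:9.3f} {r['sd']:8.3f} "
            f"{r['lo']:9.3f} {r['hi']:9.3f} {marks.get(r['flag'], '')}")
    return "\n".join(lines)


def table1_csv(table: pd.DataFrame) -> str:
    """Serialize a rendered table to CSV text (see :func:`parse_table1_csv`)."""
    buf = StringIO()
    table.to_csv(buf, index=False)
    return buf.getvalue()


def parse_table1_csv(text: str) -> pd.DataFrame:
    """Inverse of :func:`table1_csv`."""
    return pd.read_csv(StringIO(text), keep_default_na=False,
                       na_values=[""], dtype={"flag": str})
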