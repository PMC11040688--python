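"""Group comparison statistics, dataset pooling, and keyword contrasts.

Implements the summary-table statistics — pooled two-sample t-test,
Cohen's d with a large-sample 95% confidence interval, and prediction
MSE — plus raw-data pooling for mega-analysis and a per-word chi-square
contrast between correct and incorrect statements with Bonferroni
correction.

The t and chi-square statistics are computed from their textbook
formulas (p-values from the scipy reference distributions); the test
suite cross-checks them against independent scipy routines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import StatementRecord, Tokenizer, default_tokenizer
from .errors import DegenerateDataError, InputFormatError

__all__ = [
    "GroupComparison",
    "KeywordResult",
    "two_group_test",
    "pool_datasets",
    "keyword_chisq",
    "render_results_table",
    "write_results_table",
    "read_results_table",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Two-group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Incorrect-vs-correct comparison for one measure.

    Means are reported with incorrect first (column I) then correct
    (column C); Cohen's d = (I - C) / pooled sd, so d < 0 means correct
    statements scored higher.  The 95% CI for d uses the large-sample
    normal approximation se(d) = sqrt(N/(n_I n_C) + d^2 / (2 df)).
    """

    measure: str
    language: str
    n: int
    n_incorrect: int
    n_correct: int
    mean_incorrect: float
    mean_correct: float
    t: float
    df: int
    p: float
    cohens_d: float
    d_ci: tuple[float, float]
    mse: float | None = None


def two_group_test(
    scores: np.ndarray,
    labels: np.ndarray,
    measure: str = "",
    language: str = "",
    mse: float | None = None,
) -> GroupComparison:
    """Pooled two-sample t-test of scores between accuracy classes.

    ``labels`` are binary (0 = incorrect, 1 = correct).  Raises
    :class:`DegenerateDataError` if a class is empty or the pooled
    variance is zero.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    inc = scores[labels == 0]
    cor = scores[labels == 1]
    n1, n2 = len(inc), len(cor)
    if n1 == 0 or n2 == 0:
        raise DegenerateDataError("both accuracy classes must be present")
    if n1 + n2 < 3:
        raise DegenerateDataError("too few observations for a t-test")
    m1, m2 = float(inc.mean()), float(cor.mean())
    df = n1 + n2 - 2
    pooled_var = (
        ((n1 - 1) * inc.var(ddof=1) if n1 > 1 else 0.0)
        + ((n2 - 1) * cor.var(ddof=1) if n2 > 1 else 0.0)
    ) / df
    if pooled_var <= 0.0:
        if m1 == m2:
            # identical constant groups: a well-defined null result
            return GroupComparison(
                measure, language, n1 + n2, n1, n2, m1, m2,
                t=0.0, df=df, p=1.0, cohens_d=0.0, d_ci=(0.0, 0.0), mse=mse,
            )
        raise DegenerateDataError("zero pooled variance with unequal means")
    sp = math.sqrt(pooled_var)
    t = (m1 - m2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = (m1 - m2) / sp
    se_d = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * df))
    zcrit = float(stats.norm.ppf(0.975))
    return GroupComparison(
        measure=measure,
        language=language,
        n=n1 + n2,
        n_incorrect=n1,
        n_correct=n2,
        mean_incorrect=m1,
        mean_correct=m2,
        t=t,
        df=df,
        p=p,
        cohens_d=d,
        d_ci=(d - zcrit * se_d, d + zcrit * se_d),
        mse=mse,
    )


# ---------------------------------------------------------------------------
# Mega-analysis pooling
# ---------------------------------------------------------------------------


def pool_datasets(
    datasets: Sequence[tuple[str, Sequence[StatementRecord]]],
) -> list[StatementRecord]:
    """Concatenate statement tables for a mega-analysis.

    Statement ids and theme labels are namespaced with the dataset id
    (``ds:sid`` / ``ds:theme``) so that folds never mix topics across
    studies and id collisions are impossible by construction; a
    collision after prefixing (duplicate dataset ids, say) is an error.
    """
    pooled: list[StatementRecord] = []
    seen: set[str] = set()
    for ds_id, statements in datasets:
        for s in statements:
            sid = f"{ds_id}:{s.statement_id}"
            if sid in seen:
                raise InputFormatError(f"statement id collision after prefixing: {sid}")
            seen.add(sid)
            pooled.append(
                StatementRecord(
                    statement_id=sid,
                    text=s.text,
                    theme=f"{ds_id}:{s.theme}",
                    accuracy=s.accuracy,
                )
            )
    return pooled


# ---------------------------------------------------------------------------
# Keyword chi-square contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeywordResult:
    """Chi-square contrast of one word between accuracy classes.

    ``count_*`` are token occurrences; ``statements_*`` are the numbers
    of statements containing the word.  ``signed`` is the chi-square
    statistic signed by direction (+ = relatively more frequent in
    correct statements), used for the left/right layout of results.
    """

    word: str
    count_incorrect: int
    count_correct: int
    statements_incorrect: int
    statements_correct: int
    chi2: float
    p: float
    signed: float
    significant: bool


def _pearson_chi2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def keyword_chisq(
    statements: Sequence[StatementRecord],
    alpha: float = 0.05,
    coding: str = "tokens",
    min_count: int = 5,
    tokenizer: Tokenizer | None = None,
) -> list[KeywordResult]:
    """Per-word chi-square tests of frequency differences between classes.

    With ``coding="tokens"`` (default) each word's 2x2 table is
    occurrences of the word vs occurrences of all other words, split by
    statement class; ``coding="presence"`` uses statements containing
    the word vs statements not containing it.  Words whose total count
    on the tested margin (token occurrences for ``"tokens"``, statement
    frequency for ``"presence"``) falls below ``min_count`` are excluded
    — the chi-square approximation needs adequate expected counts — and
    the Bonferroni threshold is alpha / m with m = words actually
    tested.  Results are sorted by signed association: most
    incorrect-leaning first, most correct-leaning last.

    Note that token-count coding treats tokens as independent; repeated
    uses of a word inside one statement violate that, so its p-values
    run anticonservative under bursty words.  Presence coding is the
    calibrated variant.
    """
    if coding not in ("tokens", "presence"):
        raise ValueError(f"unknown coding {coding!r}")
    tok = tokenizer or default_tokenizer
    tok_counts: dict[str, list[int]] = {}
    stmt_counts: dict[str, list[int]] = {}
    n_statements = [0, 0]
    total_tokens = [0, 0]
    for s in statements:
        tokens = tok(s.text)
        cls = s.accuracy
        n_statements[cls] += 1
        total_tokens[cls] += len(tokens)
        for w in tokens:
            tok_counts.setdefault(w, [0, 0])[cls] += 1
        for w in set(tokens):
            stmt_counts.setdefault(w, [0, 0])[cls] += 1
    if n_statements[0] == 0 or n_statements[1] == 0:
        raise DegenerateDataError("both accuracy classes must be present")

    margin = tok_counts if coding == "tokens" else stmt_counts
    tested = sorted(w for w, c in margin.items() if c[0] + c[1] >= min_count)
    if len(tested) < 2:
        raise DegenerateDataError(
            f"fewer than 2 unique words pass the min_count={min_count} filter"
        )
    m = len(tested)
    threshold = alpha / m
    results: list[KeywordResult] = []
    for w in tested:
        ci, cc = tok_counts[w]
        si, sc = stmt_counts[w]
        if coding == "tokens":
            a, b = ci, total_tokens[0] - ci
            c, d = cc, total_tokens[1] - cc
            rate_i = ci / total_tokens[0] if total_tokens[0] else 0.0
            rate_c = cc / total_tokens[1] if total_tokens[1] else 0.0
        else:
            a, b = si, n_statements[0] - si
            c, d = sc, n_statements[1] - sc
            rate_i = si / n_statements[0]
            rate_c = sc / n_statements[1]
        chi2 = _pearson_chi2(a, b, c, d)
        p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
        sign = 0.0 if rate_i == rate_c else (1.0 if rate_c > rate_i else -1.0)
        results.append(
            KeywordResult(
                word=w,
                count_incorrect=ci,
                count_correct=cc,
                statements_incorrect=si,
                statements_correct=sc,
                chi2=chi2,
                p=p,
                signed=sign * chi2,
                significant=p <= threshold,
            )
        )
    results.sort(key=lambda r: (r.signed, r.word))
    n_sig = sum(r.significant for r in results)
    logger.info(
        "keyword analysis: %d words tested, %d significant at alpha=%g (Bonferroni)",
        m, n_sig, alpha,
    )
    return results


# ---------------------------------------------------------------------------
# Results table rendering
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["Study", "Measure", "Language", "N", "I", "C", "p", "t", "d [CI]", "MSE"]


def _format_p(p: float) -> str:
    stars = "**" if p < 0.001 else ("*" if p < 0.01 else "")
    return f"{p:.4f}{stars}"


def render_results_table(
    comparisons: Sequence[GroupComparison],
    studies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Format comparisons as a deterministic summary table.

    Column order Study | Measure | Language | N | I | C | p | t | d [CI]
    | MSE, with the star convention ``**`` for p < 0.001 and ``*`` for
    p < 0.01.
    """
    if studies is None:
        studies = ["1"] * len(comparisons)
    if len(studies) != len(comparisons):
        raise ValueError("studies and comparisons must be aligned")
    rows = []
    for study, cmp_ in zip(studies, comparisons):
        rows.append(
            {
                "Study": study,
                "Measure": cmp_.measure,
                "Language": cmp_.language,
                "N": str(cmp_.n),
                "I": f"{cmp_.mean_incorrect:.2f}",
                "C": f"{cmp_.mean_correct:.2f}",
                "p": _format_p(cmp_.p),
                "t": f"{cmp_.t:.2f}",
                "d [CI]": (
                    f"{cmp_.cohens_d:.2f} "
                    f"[{cmp_.d_ci[0]:.2f}, {cmp_.d_ci[1]:.2f}]"
                ),
                "MSE": "" if cmp_.mse is None else f"{cmp_.mse:.2f}",
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
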