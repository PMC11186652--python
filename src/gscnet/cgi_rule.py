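"""Corpus-predominant gastritis index (CGI) decision rule.

Under the updated Sydney system each gastric section (antrum, body, cardia)
receives an acute inflammation score (AIS) and a chronic inflammation score
(CIS), each graded 0-3.  The two grades are combined into a per-section
inflammation score (IS); the CGI diagnosis then compares the antrum IS against
the corpus sections:

    CGI = 1  if  IS_A < IS_B,
    CGI = 1  if  IS_A <= IS_C  and  IS_C != 1,
    CGI = 0  otherwise.

The rule is implemented literally, including the consequence that an all-zero
profile is labelled positive; ``require_corpus_inflammation=True`` opts into
additionally requiring max(IS_B, IS_C) > 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import pandas as pd

__all__ = [
    "SectionScores",
    "InflammationProfile",
    "GRADE_RANGE",
    "combine_is",
    "diagnose_cgi",
    "rule_table",
]

GRADE_RANGE = range(0, 4)  # AIS/CIS grades
IS_RANGE = range(0, 7)  # combined IS under the default sum operator

#: Combination strategies mapping (AIS, CIS) -> IS.  "sum" is the default.
COMBINERS: dict[str, Callable[[int, int], int]] = {
    "sum": lambda a, c: a + c,
    "max": lambda a, c: max(a, c),
}


def _check_grade(value: int, field: str) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValueError(f"{field} must be an integer grade, got {value!r}")
    if value not in GRADE_RANGE:
        raise ValueError(f"{field} must be in {{0,1,2,3}}, got {value}")


@dataclass(frozen=True)
class SectionScores:
    """Per-section acute (AIS) and chronic (CIS) inflammation grades."""

    ais_antrum: int
    cis_antrum: int
    ais_body: int
    cis_body: int
    ais_cardia: int
    cis_cardia: int

    def __post_init__(self) -> None:
        for field in (
            "ais_antrum",
            "cis_antrum",
            "ais_body",
            "cis_body",
            "ais_cardia",
            "cis_cardia",
        ):
            _check_grade(getattr(self, field), field)

    def profile(self, combiner: str = "sum") -> "InflammationProfile":
        """Combine the six grades into the three per-section IS values."""
        return InflammationProfile(
            is_antrum=combine_is(self.ais_antrum, self.cis_antrum, combiner),
            is_body=combine_is(self.ais_body, self.cis_body, combiner),
            is_cardia=combine_is(self.ais_cardia, self.cis_cardia, combiner),
        )


@dataclass(frozen=True)
class InflammationProfile:
    """Combined inflammation scores (IS) of the antrum, body and cardia."""

    is_antrum: int
    is_body: int
    is_cardia: int

    def __post_init__(self) -> None:
        for field in ("is_antrum", "is_body", "is_cardia"):
            value = getattr(self, field)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValueError(f"{field} must be an integer, got {value!r}")
            if not 0 <= value <= 6:
                raise ValueError(f"{field} must be in 0..6, got {value}")


def combine_is(ais: int, cis: int, combiner: str = "sum") -> int:
    """Combine an AIS and a CIS grade into one inflammation score.

    The default operator is the arithmetic sum, giving IS in 0..6.
    """
    _check_grade(ais, "ais")
    _check_grade(cis, "cis")
    try:
        fn = COMBINERS[combiner]
    except KeyError:
        raise ValueError(
            f"unknown combiner {combiner!r}; choose from {sorted(COMBINERS)}"
        ) from None
    return fn(ais, cis)


def diagnose_cgi(
    profile: InflammationProfile, *, require_corpus_inflammation: bool = False
) -> int:
    """Apply the CGI decision rule to an inflammation profile.

    Returns 1 (CGI present, high gastric-cancer risk) iff IS_A < IS_B, or
    IS_A <= IS_C with IS_C != 1.  With ``require_corpus_inflammation`` the
    all-quiet corpus (IS_B = IS_C = 0) is forced negative; the literal rule
    labels it positive.
    """
    a, b, c = profile.is_antrum, profile.is_body, profile.is_cardia
    positive = (a < b) or (a <= c and c != 1)
    if require_corpus_inflammation and max(b, c) == 0:
        positive = False
    return int(positive)


def rule_table(*, require_corpus_inflammation: bool = False) -> pd.DataFrame:
    """Exhaustively enumerate the rule over all 343 IS triples.

    Rows are lexicographic in (IS_A, IS_B, IS_C); columns are
    ``is_antrum, is_body, is_cardia, cgi``.
    """
    rows = [
        (
            a,
            b,
            c,
            diagnose_cgi(
                InflammationProfile(a, b, c),
                require_corpus_inflammation=require_corpus_inflammation,
            ),
        )
        for a, b, c in itertools.product(IS_RANGE, IS_RANGE, IS_RANGE)
    ]
    return pd.DataFrame(rows, columns=["is_antrum", "is_body", "is_cardia", "cgi"])
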