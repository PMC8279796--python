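"""Random expression generation for stress-testing the evaluator.

Builds small random query ASTs over a supplied code pool, covering every
construct the day-set interpreter understands; used to cross-check the
interval-algebra evaluator against the day-membership semantics on many
thousands of cases.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .algebra import ABSENCE, PRESENCE, STAR_FIRST, STAR_SECOND, WindowModifier
from .parser import (Age, Count, Expression, Feature, Labs, Nary, SequenceOp,
                     Text, Unary, Year)

_LEAF_KINDS = ("feature", "feature", "feature", "labs", "age", "gender", "text", "year")
_NODE_KINDS = ("UNION", "INTERSECT", "AND", "OR", "NOT", "DIFF", "INVERT",
               "FIRST_MENTION", "NO_HISTORY_OF", "NEVER_HAD", "COUNT",
               "SEQUENCE", "ORIGINAL")


def random_expression(rng: np.random.Generator,
                      pools: Dict[str, Sequence[str]],
                      depth: int = 3,
                      lab_code: str = "4548-4 [%]",
                      text_phrases: Sequence[str] = ("cough", "chest pain"),
                      year_range=(2005, 2025)) -> Expression:
    """A random expression of at most ``depth`` operator levels.

    ``pools`` maps coded namespaces (ICD9/ICD10/CPT/RX/...) to candidate
    codes; other leaves draw from ``lab_code``, ``text_phrases`` and AGE/YEAR
    windows.
    """

    def pick(seq):
        return seq[int(rng.integers(0, len(seq)))]

    def leaf() -> Expression:
        kind = pick(_LEAF_KINDS)
        if kind == "feature":
            namespaces = [ns for ns in pools if pools[ns]]
            ns = pick(namespaces)
            return Feature(ns, pick(list(pools[ns])))
        if kind == "labs":
            lo = float(rng.integers(4, 10))
            return Labs(lab_code, lo, None if rng.random() < 0.5 else lo + 3.0)
        if kind == "age":
            lo = int(rng.integers(0, 80)) * 365
            return Age(lo, None if rng.random() < 0.5 else lo + int(rng.integers(1, 30)) * 365)
        if kind == "gender":
            return Feature("GENDER", pick(["male", "female"]))
        if kind == "text":
            return Text(pick(list(text_phrases)), frozenset())
        lo = int(rng.integers(year_range[0], year_range[1]))
        return Year(lo, lo + int(rng.integers(0, 5)))

    def build(d: int) -> Expression:
        if d <= 0 or rng.random() < 0.3:
            return leaf()
        op = pick(_NODE_KINDS)
        if op in ("UNION", "INTERSECT", "AND", "OR", "NOT"):
            n = int(rng.integers(1, 4))
            return Nary(op, tuple(build(d - 1) for _ in range(n)))
        if op == "DIFF":
            return Nary("DIFF", (build(d - 1), build(d - 1)))
        if op in ("INVERT", "FIRST_MENTION", "NO_HISTORY_OF", "NEVER_HAD"):
            return Unary(op, build(d - 1))
        if op == "ORIGINAL":
            return Unary("ORIGINAL", leaf())
        if op == "COUNT":
            lo = int(rng.integers(0, 4))
            hi = None if rng.random() < 0.5 else lo + int(rng.integers(0, 4))
            return Count(build(d - 1), lo, hi)
        # SEQUENCE
        star = STAR_FIRST if rng.random() < 0.5 else STAR_SECOND
        window = None
        if rng.random() < 0.5:
            lo = int(rng.integers(-400, 200))
            hi = lo + int(rng.integers(0, 400))
            window = WindowModifier(PRESENCE if rng.random() < 0.5 else ABSENCE,
                                    None if rng.random() < 0.1 else lo,
                                    None if rng.random() < 0.1 else hi)
        return SequenceOp(build(d - 1), build(d - 1), star, window)

    return build(depth)
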