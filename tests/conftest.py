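"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
import re

import pytest

from alkbtyper.motif_scan import MotifPattern, default_patterns
from alkbtyper.synth_fixtures import FixtureSpec, make_alkb_protein


@pytest.fixture(scope="session")
def strict_patterns():
    return default_patterns("strict")


@pytest.fixture(scope="session")
def generalized_patterns():
    return default_patterns("generalized")


@pytest.fixture(scope="session")
def canonical_protein():
    return make_alkb_protein(FixtureSpec(label="canonical", seed=1))


@pytest.fixture(scope="session")
def alkb0_protein():
    return make_alkb_protein(FixtureSpec(label="alkb0", seed=1))


def pattern_to_regex(pattern: MotifPattern) -> re.Pattern:
    """Independent oracle: compile a motif pattern to a regex.

    Used with a lookahead to enumerate overlapping matches; X is excluded
    from constrained positions by construction (character classes list only
    the allowed residues).
    """
    parts = []
    for allowed in pattern.positions:
        if allowed is None:
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(allowed)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def regex_scan(seq: str, patterns) -> list[tuple[str, int, str]]:
    """All (motif_id, start, match) occurrences via the regex oracle."""
    hits = []
    for p in patterns:
        rx = pattern_to_regex(p)
        for m in rx.finditer(seq):
            hits.append((p.motif_id, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


# --- independent Gotoh global-alignment oracle -------------------------------


def gotoh_align(a: str, b: str, score, gap_open: int = 10, gap_extend: int = 1):
    """Affine-gap Needleman-Wunsch (Gotoh) with deterministic traceback.

    ``score(x, y)`` supplies substitution scores.  Terminal gaps are
    penalized.  Returns (optimal score, aligned_a, aligned_b).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
    best = max(M[n][m], X[n][m], Y[n][m])
    # traceback (prefer M, then X, then Y on ties)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n][m])
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == "M":
            s = score(a[i - 1], b[j - 1])
            prev = M[i][j] - s
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i - 1][j - 1] - prev) < 1e-9:
                    state = st
                    break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 and abs(X[i - 1][j] - gap_extend - X[i][j]) < 1e-9:
                state = "X"
            else:
                state = "M"
            i -= 1
            if i == 0 and j > 0:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 and abs(Y[i][j - 1] - gap_extend - Y[i][j]) < 1e-9:
                state = "Y"
            else:
                state = "M"
            j -= 1
            if j == 0 and i > 0:
                state = "X"
    return best, "".join(reversed(out_a)), "".join(reversed(out_b))
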