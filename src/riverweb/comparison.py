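"""Two-web centrality comparison (shared-node harmonization + Mann-Whitney).

Food webs compiled for different rivers name overlapping taxa
inconsistently (family code vs genus, size/age-split species vs
species), so shared nodes are matched by normalized label equality
plus an explicit synonym list.  The matched nDC and nBC columns are
then compared with two-sample Mann-Whitney tests computed on midranks,
reporting U = min(U1, U2) and a two-sided asymptotic p-value with tie
correction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm, rankdata

from .core import CentralityTable, ValidationError, normalize_label

__all__ = [
    "ComparisonResult",
    "match_shared_nodes",
    "median",
    "mann_whitney",
    "compare_tables",
    "read_synonyms",
]


class AmbiguityError(ValueError):
    """A label matches more than one partner across the two tables."""


@dataclass
class ComparisonResult:
    shared: list[tuple[str, str]]
    medians: dict[str, dict[str, float]]  # metric -> {"A": ..., "B": ...}
    tests: dict[str, dict[str, float]]  # metric -> {"U": ..., "p": ..., "n": ...}
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.shared)

    def as_dict(self) -> dict:
        return {
            "n_shared": self.n,
            "shared": [list(p) for p in self.shared],
            "medians": self.medians,
            "tests": self.tests,
            "unmatched_a": self.unmatched_a,
            "unmatched_b": self.unmatched_b,
        }


def read_synonyms(path) -> list[tuple[str, str]]:
    """Read a synonym CSV with columns ``label_a,label_b``."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        reader.fieldnames = [f.strip().lower() for f in reader.fieldnames or []]
        for row in reader:
            a = (row.get("label_a") or "").strip()
            b = (row.get("label_b") or "").strip()
            if a and b:
                pairs.append((a, b))
    return pairs


def match_shared_nodes(
    table_a: CentralityTable,
    table_b: CentralityTable,
    synonyms: list[tuple[str, str]] | None = None,
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Pair up the nodes the two webs share.

    Returns (matched pairs, unmatched A labels, unmatched B labels).
    Matching is by normalized label equality, extended by the explicit
    synonym pairs (A label, B label).  A label that would match two
    different partners raises :class:`AmbiguityError`.
    """
    if not table_a.rows or not table_b.rows:
        raise ValidationError("centrality tables must be non-empty")
    syn_ab: dict[str, str] = {}
    syn_ba: dict[str, str] = {}
    for a, b in synonyms or []:
        ka, kb = normalize_label(a), normalize_label(b)
        if syn_ab.get(ka, kb) != kb or syn_ba.get(kb, ka) != ka:
            raise AmbiguityError(f"synonym conflict for {a!r}/{b!r}")
        syn_ab[ka] = kb
        syn_ba[kb] = ka
    b_by_key = {normalize_label(lab): lab for lab in table_b.rows}
    pairs: list[tuple[str, str]] = []
    used_b: set[str] = set()
    for label_a in table_a.rows:
        ka = normalize_label(label_a)
        candidates = []
        direct = b_by_key.get(ka)
        if direct is not None:
            candidates.append(direct)
        via_syn = b_by_key.get(syn_ab.get(ka, ""))
        if via_syn is not None and via_syn not in candidates:
            candidates.append(via_syn)
        if len(candidates) > 1:
            raise AmbiguityError(f"{label_a!r} matches both {candidates[0]!r} and {candidates[1]!r}")
        if candidates:
            partner = candidates[0]
            if partner in used_b:
                raise AmbiguityError(f"{partner!r} matched twice")
            used_b.add(partner)
            pairs.append((label_a, partner))
    unmatched_a = [lab for lab in table_a.rows if lab not in {p[0] for p in pairs}]
    unmatched_b = [lab for lab in table_b.rows if lab not in used_b]
    return pairs, unmatched_a, unmatched_b


def median(values) -> float:
    """Middle order statistic; mean of the two middle values for even n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("median of empty sample")
    return float(np.median(arr))


def mann_whitney(
    sample_a, sample_b, *, exact: bool = False
) -> tuple[float, float]:
    """Two-sample Mann-Whitney test on midranks.

    Returns ``(U, p)`` with U = min(U1, U2) — the convention under
    which complete group separation gives U = 0 — and a two-sided
    p-value.  The default p is the normal approximation with
    tie-corrected variance and no continuity correction; ``exact=True``
    enumerates the permutation distribution (only sensible for small
    samples, and only valid without ties across groups).
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValidationError("degenerate samples: all values identical")
    ranks = rankdata(pooled)  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if exact:
        from scipy.stats import mannwhitneyu

        p = float(mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
        return float(u), p
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValidationError("zero variance after tie correction")
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return float(u), min(p, 1.0)


def compare_tables(
    table_a: CentralityTable,
    table_b: CentralityTable,
    synonyms: list[tuple[str, str]] | None = None,
    *,
    exact: bool = False,
) -> ComparisonResult:
    """Full shared-node comparison of two centrality tables."""
    pairs, un_a, un_b = match_shared_nodes(table_a, table_b, synonyms)
    if not pairs:
        raise ValidationError("no shared nodes")
    cols = {"ndc": 0, "nbc": 1}
    medians: dict[str, dict[str, float]] = {}
    tests: dict[str, dict[str, float]] = {}
    for metric, idx in cols.items():
        va = [table_a.rows[la][idx] for la, _ in pairs]
        vb = [table_b.rows[lb][idx] for _, lb in pairs]
        medians[metric] = {table_a.name: median(va), table_b.name: median(vb)}
        u, p = mann_whitney(va, vb, exact=exact)
        tests[metric] = {"U": u, "p": p, "n": len(pairs)}
    return ComparisonResult(
        shared=pairs, medians=medians, tests=tests, unmatched_a=un_a, unmatched_b=un_b
    )
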