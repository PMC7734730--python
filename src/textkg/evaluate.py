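"""Triple-set comparison: normalization, set differences, Jaccard similarity.

Two triple sets (e.g. one extracted automatically, one transcribed by a
domain expert) are compared after canonicalization: equality is exact
string equality of (subject, predicate, object) once literals are
case-folded, whitespace-collapsed and stripped of leading determiners.
The Jaccard coefficient J(A, B) = |A ∩ B| / |A ∪ B| summarizes the
overlap; it is 1 for identical (or both-empty) sets and 0 for disjoint
ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import TextKgError
from .extract import DETERMINERS, Term, Triple, read_triples_tsv


def _normalize_literal(value: str, strip_determiners: bool) -> str:
    tokens = " ".join(value.casefold().split()).split()
    if strip_determiners:
        while tokens and tokens[0] in DETERMINERS:
            tokens.pop(0)
    return " ".join(tokens)


def normalize_triple(t: Triple) -> Triple:
    """Canonical form for comparison; idempotent.

    Literals are case-folded and whitespace-collapsed; subject/object
    literals additionally lose leading determiners.  IRI terms are kept
    verbatim.
    """

    def norm(term: Term, position: str) -> Term:
        if term.kind != "literal":
            return term
        normalized = _normalize_literal(term.value, strip_determiners=position != "predicate")
        return Term("literal", normalized) if normalized else term
    return Triple(
        norm(t.subject, "subject"),
        norm(t.predicate, "predicate"),
        norm(t.object, "object"),
        t.provenance,
        t.sentence_id,
    )


def jaccard(a: Iterable[Triple], b: Iterable[Triple]) -> float:
    """|a ∩ b| / |a ∪ b| over normalized triple sets; 1.0 when both empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


@dataclass(frozen=True)
class TripleSetComparison:
    """Counts of triples unique to each set, shared, and their Jaccard."""

    only_a: int
    only_b: int
    both: int
    jaccard: float

    def __post_init__(self):
        if self.only_a == self.only_b == self.both == 0:
            expected = 1.0
        else:
            expected = self.both / (self.only_a + self.only_b + self.both)
        if not math.isclose(self.jaccard, expected, rel_tol=0, abs_tol=1e-12):
            raise TextKgError(
                f"inconsistent comparison: jaccard {self.jaccard} != {expected}"
            )

    def to_dict(self) -> dict:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "both": self.both,
            "jaccard": self.jaccard,
        }


def diff_triple_sets(a: Iterable[Triple], b: Iterable[Triple]) -> TripleSetComparison:
    """Set difference/intersection counts plus the Jaccard coefficient."""
    a, b = set(a), set(b)
    both = len(a & b)
    return TripleSetComparison(len(a - b), len(b - a), both, jaccard(a, b))


def round_score(value: float, ndigits: int = 2, mode: str = "half_even") -> float:
    """Report rounding: banker's rounding by default, truncation on request."""
    if mode == "half_even":
        return round(value, ndigits)
    if mode == "truncate":
        factor = 10 ** ndigits
        return math.floor(value * factor) / factor
    raise TextKgError(f"unknown rounding mode {mode!r}")


def load_normalized_triple_set(path: str | Path) -> set[Triple]:
    """Read a triples TSV intermediate and normalize it for comparison."""
    return {normalize_triple(t) for t in read_triples_tsv(path)}


def write_comparison(
    comparison: TripleSetComparison, path: str | Path, rounding: str = "half_even"
) -> None:
    """Write the comparison as JSON (``.json``) or TSV (anything else)."""
    path = Path(path)
    rounded = round_score(comparison.jaccard, mode=rounding)
    if path.suffix == ".json":
        payload = comparison.to_dict()
        payload["jaccard_rounded"] = rounded
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        lines = [
            "# only_a\tonly_b\tboth\tjaccard",
            f"{comparison.only_a}\t{comparison.only_b}\t{comparison.both}\t{rounded:.2f}",
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
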