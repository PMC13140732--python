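"""Levenshtein similarity scoring and candidate ranking.

Generated candidates that survive the physicochemical screen are
ranked against a reference peptide (by default QK, the VEGF-mimetic
15-mer) by normalised Levenshtein similarity

    sim(a, b) = 1 - d(a, b) / max(|a|, |b|)

where d is the unit-cost edit distance.  Ties are broken by raw edit
distance, then lexicographically, so a ranking is a pure function of
the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .properties import PropertyProfile
from .synthetic import QK_SEQUENCE


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions).

    Standard two-row dynamic programme; empty strings allowed.
    """
    if len(a) < len(b):  # iterate over the longer string
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,          # deletion from a
                    cur[j - 1] + 1,       # insertion into a
                    prev[j - 1] + (ca != cb),  # substitution / match
                )
            )
        prev = cur
    return prev[-1]


def normalized_similarity(candidate: str, reference: str) -> float:
    """``1 - d / max(len(candidate), len(reference))``, in [0, 1]."""
    if not reference:
        raise ValueError("reference peptide must be non-empty")
    return 1.0 - levenshtein(candidate, reference) / max(
        len(candidate), len(reference)
    )


@dataclass(frozen=True)
class RankedCandidate:
    """A screened candidate with its similarity score and rank."""

    sequence: str
    profile: PropertyProfile
    edit_distance: int
    normalized_similarity: float
    rank: int


def rank_candidates(
    candidates: Sequence[PropertyProfile],
    reference: str = QK_SEQUENCE,
) -> list[RankedCandidate]:
    """Rank filter-passing candidates by similarity to the reference.

    Candidates whose overall filter verdict is ``False`` are excluded.
    Sorting is by similarity descending, then edit distance ascending,
    then sequence lexicographically; ranks are assigned 1..n.
    """
    if not reference:
        raise ValueError("reference peptide must be non-empty")
    scored = []
    for profile in candidates:
        if not profile.passes:
            continue
        d = levenshtein(profile.sequence, reference)
        sim = 1.0 - d / max(len(profile.sequence), len(reference))
        scored.append((profile, d, sim))
    scored.sort(key=lambda t: (-t[2], t[1], t[0].sequence))
    return [
        RankedCandidate(
            sequence=p.sequence,
            profile=p,
            edit_distance=d,
            normalized_similarity=sim,
            rank=i,
        )
        for i, (p, d, sim) in enumerate(scored, start=1)
    ]


def ranking_to_tsv(ranked: Sequence[RankedCandidate], path) -> None:
    """Write a ranked candidate table as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "rank\tsequence\tsimilarity\tedit_distance\tlength\tmw"
            "\tgravy\tnet_charge\tpi\n"
        )
        for rc in ranked:
            p = rc.profile
            fh.write(
                f"{rc.rank}\t{rc.sequence}\t{rc.normalized_similarity:.4f}"
                f"\t{rc.edit_distance}\t{p.length}\t{p.mw:.2f}"
                f"\t{p.gravy:.4f}\t{p.net_charge:+d}\t{p.pi:.3f}\n"
            )
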