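"""Peptide corpus I/O and curation.

A training corpus for the sequence generator is a set of short peptides
(here, 8-20 residues) curated for diversity: after length banding,
redundant sequences are removed so that no retained pair exceeds a
global sequence-identity threshold (30% by default).  Identity is
defined on a Needleman-Wunsch global alignment with match +1,
mismatch 0 and linear gap penalty -1; the identity of a pair is the
number of identical aligned columns divided by the alignment length,
with gap columns counted in the denominator.  Among equally optimal
alignments the one maximising the identical-column count is used,
which makes the metric well defined (and, for this scoring scheme,
also maximises the identity fraction itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence with a provenance tag.

    Parameters
    ----------
    id : str
        Short unique label within a corpus.
    sequence : str
        Uppercase string over the 20 standard one-letter codes.
    source : str
        Free-text provenance tag (e.g. a database accession, or
        ``"synthetic"``).
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}; "
                f"sequences must use the 20 standard one-letter codes"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CurationReport:
    """Bookkeeping for a curation run.

    ``removed_pairs`` lists, for every dropped record, the already-kept
    record whose identity with it met the threshold.
    """

    n_input: int = 0
    n_after_length: int = 0
    n_after_identity: int = 0
    removed_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        """Write the removed pairs as TSV (kept_id, dropped_id, identity)."""
        with open(path, "w") as fh:
            fh.write("kept_id\tdropped_id\tidentity\n")
            for kept, dropped, ident in self.removed_pairs:
                fh.write(f"{kept}\t{dropped}\t{ident:.6f}\n")


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptides from a FASTA file.

    Sequences are uppercased; entries containing characters outside
    the 20-letter alphabet are rejected with a logged warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If no valid record remains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[PeptideRecord] = []
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        try:
            rec = PeptideRecord(id=entry.id, sequence=seq, source=str(path))
        except ValueError as exc:
            logger.warning("skipping FASTA entry %r: %s", entry.id, exc)
            continue
        if rec.id in seen_ids:
            logger.warning("skipping FASTA entry with duplicate id %r", rec.id)
            continue
        seen_ids.add(rec.id)
        records.append(rec)
    if not records:
        raise ValueError(f"no valid peptide records in {path}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write peptides as FASTA, sequences wrapped at 60 columns."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.source)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def filter_length_band(
    records: Sequence[PeptideRecord], min_len: int, max_len: int
) -> list[PeptideRecord]:
    """Keep records with ``min_len <= length <= max_len``, order preserved."""
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid length band ({min_len}, {max_len})")
    return [r for r in records if min_len <= len(r) <= max_len]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity of two peptides, in [0, 1].

    Needleman-Wunsch with match +1, mismatch 0, linear gap -1.
    Identity = identical columns / alignment length, maximised over all
    optimal-score alignments (the maximum is computed exactly from the
    DP matrices, not from a single traceback).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    m, n = len(a), len(b)

    # forward scores F[i][j]: best score aligning a[:i] with b[:j]
    F = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        F[i][0] = -float(i)
    for j in range(n + 1):
        F[0][j] = -float(j)
    for i in range(1, m + 1):
        ai = a[i - 1]
        Fi, Fp = F[i], F[i - 1]
        for j in range(1, n + 1):
            diag = Fp[j - 1] + (1.0 if ai == b[j - 1] else 0.0)
            Fi[j] = max(diag, Fp[j] - 1.0, Fi[j - 1] - 1.0)

    # backward scores B[i][j]: best score aligning a[i:] with b[j:]
    B = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        B[i][n] = -float(m - i)
    for j in range(n + 1):
        B[m][j] = -float(n - j)
    for i in range(m - 1, -1, -1):
        ai = a[i]
        Bi, Bn = B[i], B[i + 1]
        for j in range(n - 1, -1, -1):
            diag = Bn[j + 1] + (1.0 if ai == b[j] else 0.0)
            Bi[j] = max(diag, Bn[j] - 1.0, Bi[j + 1] - 1.0)

    opt = F[m][n]
    NEG = float("-inf")
    # max identical columns along any optimal-score path: a DP edge is
    # usable iff forward score + edge weight + backward score == opt
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            best = NEG
            bij = B[i][j]
            if i > 0 and j > 0:
                w = 1.0 if a[i - 1] == b[j - 1] else 0.0
                if F[i - 1][j - 1] + w + bij == opt and M[i - 1][j - 1] > NEG:
                    best = M[i - 1][j - 1] + w
            if i > 0 and F[i - 1][j] - 1.0 + bij == opt and M[i - 1][j] > NEG:
                best = max(best, M[i - 1][j])
            if j > 0 and F[i][j - 1] - 1.0 + bij == opt and M[i][j - 1] > NEG:
                best = max(best, M[i][j - 1])
            M[i][j] = best

    matches = M[m][n]
    # score = matches - gap columns, so gaps = matches - opt and
    # alignment length = (m + n + gaps) / 2
    length = (m + n + matches - opt) / 2.0
    return matches / length


def deduplicate_by_identity(
    records: Sequence[PeptideRecord], threshold: float = 0.30
) -> tuple[list[PeptideRecord], CurationReport]:
    """Greedy redundancy removal at a pairwise-identity threshold.

    Records are scanned in input order; a record is kept iff its
    identity with every already-kept record is strictly below
    ``threshold``.  The report lists each drop with the kept record
    that triggered it.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[PeptideRecord] = []
    report = CurationReport(
        n_input=len(records), n_after_length=len(records)
    )
    for rec in records:
        trigger = None
        for k in kept:
            ident = pairwise_identity(rec.sequence, k.sequence)
            if ident >= threshold:
                trigger = (k.id, rec.id, ident)
                break
        if trigger is None:
            kept.append(rec)
        else:
            report.removed_pairs.append(trigger)
    report.n_after_identity = len(kept)
    return kept, report


def curate(
    records: Sequence[PeptideRecord],
    min_len: int = 8,
    max_len: int = 20,
    identity_threshold: float = 0.30,
) -> tuple[list[PeptideRecord], CurationReport]:
    """Full curation: length banding then identity deduplication."""
    banded = filter_length_band(records, min_len, max_len)
    kept, report = deduplicate_by_identity(banded, identity_threshold)
    report.n_input = len(records)
    report.n_after_length = len(banded)
    return kept, report
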