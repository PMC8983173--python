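"""Sequence-based typing of the HLA-E promoter amplicon.

A Sanger consensus of a diploid sample encodes heterozygous positions as
IUPAC ambiguity codes (a G/T double peak base-calls as K). Typing proceeds by
superposing every unordered pair of reference alleles — including self-pairs,
so homozygotes type correctly — into the IUPAC consensus that pair would
produce, scoring each expected consensus against the observed one, and
ranking the combinations. The combination(s) with the highest score give the
typing; the genotype at a named site (NT-26 for rs76971248) is then read
directly from the observed code at that column.

The score is the count of exact per-position IUPAC code matches (Hamming
similarity). This is the simplest rule consistent with ranked-combination
output; partial credit for compatible-but-unequal codes (observed base set a
subset of the expected one) could be added later without changing the
interface. Ties are reported as a set, never broken silently: SBT ambiguity
is real and should be visible. An observed N counts as a mismatch unless the
expected code is also N — conservative and deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .allele_db import AlleleDB, SiteSpec
from .errors import InputError
from .genotype import GenotypeCall, SBT, UNKNOWN, het_label

# IUPAC nucleotide alphabet: 4 bases, 6 two-base, 4 three-base codes, and N.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: code -> frozenset of bases it denotes, e.g. "K" -> {G, T}
IUPAC_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in IUPAC_CODES
}

#: frozenset of bases -> unique code, e.g. {G, T} -> "K"
CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}


def combine_bases(base1: str, base2: str) -> str:
    """IUPAC code for the diploid superposition of two reference bases.

    Symmetric in its arguments; (G, T) -> "K", (A, A) -> "A".
    """
    try:
        return CODE_FOR_BASES[frozenset((base1, base2))]
    except KeyError:
        raise InputError(
            f"combine_bases expects plain A/C/G/T bases, got ({base1!r}, {base2!r})"
        ) from None


@dataclass(frozen=True)
class ConsensusSeq:
    """Observed (or expected) IUPAC-coded consensus sequence of one sample."""

    sample_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"sample {self.sample_id!r}: empty consensus")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise InputError(
                f"sample {self.sample_id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairScore:
    """Score of one unordered allele pair against the observed consensus."""

    allele_a: str
    allele_b: str
    score: int
    mismatch_positions: tuple[int, ...]

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))


@dataclass
class TypingResult:
    """Full ranking of allele-pair combinations for one sample."""

    sample_id: str
    ranked: list[PairScore] = field(default_factory=list)

    @property
    def best(self) -> list[PairScore]:
        """All pairs attaining the maximum score (ties preserved)."""
        if not self.ranked:
            return []
        top = self.ranked[0].score
        return [ps for ps in self.ranked if ps.score == top]

    @property
    def best_score(self) -> int:
        return self.ranked[0].score if self.ranked else 0


def expected_consensus(db: AlleleDB, allele_a: str, allele_b: str) -> ConsensusSeq:
    """Position-wise IUPAC superposition of two aligned reference alleles.

    ``expected_consensus(db, a, a)`` is exactly allele ``a``'s sequence.
    """
    sa = db.record(allele_a).region_seq
    sb = db.record(allele_b).region_seq
    if allele_a == allele_b:
        seq = sa
    else:
        seq = "".join(combine_bases(x, y) for x, y in zip(sa, sb))
    return ConsensusSeq(sample_id=f"{allele_a}+{allele_b}", seq=seq)


def score_pair(
    observed: ConsensusSeq,
    expected: ConsensusSeq,
    allele_a: str = "",
    allele_b: str = "",
) -> PairScore:
    """Exact per-position match count between observed and expected consensus."""
    if len(observed) != len(expected):
        raise InputError(
            f"length mismatch: observed {len(observed)} nt vs expected {len(expected)} nt"
        )
    mismatches = tuple(
        i for i, (o, e) in enumerate(zip(observed.seq, expected.seq)) if o != e
    )
    return PairScore(
        allele_a=allele_a,
        allele_b=allele_b,
        score=len(observed) - len(mismatches),
        mismatch_positions=mismatches,
    )


def type_sample(db: AlleleDB, observed: ConsensusSeq) -> TypingResult:
    """Score every unordered allele pair (with self-pairs) and rank by score.

    For n alleles this enumerates n(n+1)/2 combinations. Ranking is by
    descending score with a deterministic (allele_a, allele_b) tiebreak for
    stable output order; all top-score pairs remain available via ``best``.
    """
    if len(db) == 0:
        raise InputError("cannot type against an empty allele database")
    if len(observed) != db.seq_length:
        raise InputError(
            f"sample {observed.sample_id!r}: consensus length {len(observed)} "
            f"does not match database amplicon length {db.seq_length}"
        )
    scores = [
        score_pair(observed, expected_consensus(db, a, b), a, b)
        for a, b in itertools.combinations_with_replacement(sorted(db.allele_ids), 2)
    ]
    scores.sort(key=lambda ps: (-ps.score, ps.allele_a, ps.allele_b))
    return TypingResult(sample_id=observed.sample_id, ranked=scores)


def call_site_genotype(observed: ConsensusSeq, site: SiteSpec) -> GenotypeCall:
    """Genotype at a single site read off the observed IUPAC code.

    ref base -> hom-ref, alt base -> hom-alt, the two-base code for
    {ref, alt} -> het, anything else (N, a third base, a wider code) ->
    UNKNOWN.
    """
    if site.index >= len(observed):
        raise InputError(
            f"site {site.label!r} index {site.index} outside consensus of "
            f"length {len(observed)}"
        )
    code = observed.seq[site.index]
    if code == site.ref_base:
        genotype = f"{site.ref_base}/{site.ref_base}"
    elif code == site.alt_base:
        genotype = f"{site.alt_base}/{site.alt_base}"
    elif code == combine_bases(site.ref_base, site.alt_base):
        genotype = het_label(site.ref_base, site.alt_base)
    else:
        genotype = UNKNOWN
    return GenotypeCall(
        sample_id=observed.sample_id,
        site_label=site.label,
        genotype=genotype,
        method=SBT,
    )


def read_consensus_fasta(path: str | Path) -> list[ConsensusSeq]:
    """Read observed sample consensus sequences (one FASTA record per sample)."""
    seqs = [
        ConsensusSeq(sample_id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise InputError(f"no FASTA records found in {path}")
    ids = [s.sample_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate sample ids in {path}")
    return seqs


def typing_table(results: Iterable[TypingResult]) -> list[dict]:
    """Flatten typing results into rows for TSV/JSON report output."""
    rows = []
    for res in results:
        for rank, ps in enumerate(res.ranked, start=1):
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "rank": rank,
                    "allele_a": ps.allele_a,
                    "allele_b": ps.allele_b,
                    "score": ps.score,
                    "n_mismatches": len(ps.mismatch_positions),
                    "is_best": ps.score == res.best_score,
                }
            )
    return rows
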