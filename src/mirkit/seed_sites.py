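"""Canonical miRNA seed-match sites: derivation, scanning and prevalence.

A mature miRNA recognises targets chiefly through its *seed*, nucleotides
2–7 of the mature sequence.  The canonical target-site classes are defined
by Watson–Crick complementarity to the seed, optional additional pairing to
miRNA position 8, and an adenosine opposite miRNA position 1:

=============  =====================================  ======
site type      target sequence (5'→3')                length
=============  =====================================  ======
8mer           revcomp(m[2..8]) + A                   8
7mer-m8        revcomp(m[2..8])                       7
7mer-A1        revcomp(m[2..7]) + A                   7
offset-6mer    revcomp(m[3..8])                       6
6mer           revcomp(m[2..7])                       6
=============  =====================================  ======

``m`` is the mature miRNA read 5'→3' with 1-based positions.  The "A" in
8mer/7mer-A1 sites is a literal adenosine on the target, regardless of
miRNA position 1.

Scanning locates every occurrence of the 6mer core (the reverse complement
of the seed) on the transcript sense strand and classifies each occurrence
by inspecting the two flanking bases, reporting the most specific type
only.  Offset-6mer occurrences are reported separately unless subsumed by
an 8mer/7mer-m8 call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from mirkit.errors import ValidationError

logger = logging.getLogger(__name__)

RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Site classes in decreasing specificity; also the report order at a tie.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "offset-6mer", "6mer")

_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

# IUPAC nucleotide letters tolerated in transcript sequences; ambiguity
# codes never match a site.
_TRANSCRIPT_ALPHABET = set("ACGUNRYSWKMBDHV")


def _normalize_rna(seq: str, *, what: str, name: str) -> str:
    """Uppercase, convert T→U and validate a strict {A,C,G,U} alphabet."""
    seq = seq.strip().upper().replace("T", "U")
    for pos, base in enumerate(seq, start=1):
        if base not in RNA_COMPLEMENT:
            raise ValidationError(
                f"{what} {name!r}: illegal character {base!r} at position {pos}"
            )
    return seq


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (uppercase {A,C,G,U})."""
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'→3'.

    DNA input (with T) is accepted and converted to the internal RNA
    alphabet.  The sequence must be at least 8 nt so that seed positions
    1–8 exist.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _normalize_rna(self.sequence, what="miRNA", name=self.name)
        )
        if len(self.sequence) < 8:
            raise ValidationError(
                f"miRNA {self.name!r}: sequence has {len(self.sequence)} nt; "
                "at least 8 are required (positions 1-8 must exist)"
            )

    @property
    def seed(self) -> str:
        """Seed sequence, mature positions 2–7."""
        return self.sequence[1:7]


@dataclass(frozen=True)
class SeedSiteSet:
    """The five canonical target-site sequences derived from one miRNA.

    All site strings are written 5'→3' in the target (transcript) strand
    orientation.
    """

    mirna_name: str
    seed: str
    site_8mer: str
    site_7mer_m8: str
    site_7mer_A1: str
    site_offset6mer: str
    site_6mer: str

    def site(self, site_type: str) -> str:
        return {
            "8mer": self.site_8mer,
            "7mer-m8": self.site_7mer_m8,
            "7mer-A1": self.site_7mer_A1,
            "offset-6mer": self.site_offset6mer,
            "6mer": self.site_6mer,
        }[site_type]

    @property
    def m8_complement(self) -> str:
        """Target base complementary to miRNA position 8 (5' flank of the core)."""
        return self.site_7mer_m8[0]

    def as_dict(self) -> dict[str, str]:
        return {t: self.site(t) for t in SITE_TYPES}


@dataclass(frozen=True)
class SiteMatch:
    """One classified site occurrence on a transcript.

    ``start``/``end`` are 1-based inclusive positions on the transcript
    sense strand.
    """

    transcript_id: str
    start: int
    end: int
    site_type: str
    matched_seq: str


def _to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def derive_site_sequences(mirna: MatureMiRNA, *, dna: bool = False) -> SeedSiteSet:
    """Derive the five canonical site sequences for one mature miRNA.

    Parameters
    ----------
    mirna
        Validated mature miRNA.
    dna
        If true, emit the site strings in the DNA alphabet (U→T); the seed
        itself stays in the miRNA (RNA) alphabet.
    """
    m = mirna.sequence
    seed = m[1:7]  # positions 2-7
    core = revcomp_rna(seed)  # 6mer site
    m2_8 = revcomp_rna(m[1:8])  # 7mer-m8 site
    sites = {
        "site_8mer": m2_8 + "A",
        "site_7mer_m8": m2_8,
        "site_7mer_A1": core + "A",
        "site_offset6mer": revcomp_rna(m[2:8]),
        "site_6mer": core,
    }
    if dna:
        sites = {k: _to_dna(v) for k, v in sites.items()}
    return SeedSiteSet(mirna_name=mirna.name, seed=seed, **sites)


def _normalize_transcript(transcript_id: str, sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    for pos, base in enumerate(seq, start=1):
        if base not in _TRANSCRIPT_ALPHABET:
            raise ValidationError(
                f"transcript {transcript_id!r}: illegal character {base!r} at "
                f"position {pos}"
            )
        if base not in RNA_COMPLEMENT:
            logger.debug(
                "transcript %s: ambiguity code %s at position %d treated as "
                "non-matching",
                transcript_id,
                base,
                pos,
            )
    return seq


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence starts of ``needle``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_transcript(
    transcript_id: str, sequence: str, sites: SeedSiteSet
) -> list[SiteMatch]:
    """Scan one transcript for canonical sites of the given miRNA.

    Every 6mer-core occurrence is classified by its flanking bases, and the
    most specific applicable site type is reported for it (8mer > 7mer-m8 >
    7mer-A1 > 6mer).  A flank that falls outside the transcript counts as
    non-matching, so a core at a transcript boundary is reported as the
    less-specific type.  Offset-6mer occurrences are reported separately
    unless their span lies inside an already-reported 8mer/7mer-m8 span.

    Returns matches sorted by start position (specificity order at ties).
    """
    if not sequence or not sequence.strip():
        raise ValidationError(f"transcript {transcript_id!r}: empty sequence")
    seq = _normalize_transcript(transcript_id, sequence)

    core = sites.site_6mer
    m8c = sites.m8_complement
    matches: list[SiteMatch] = []
    strong_spans: list[tuple[int, int]] = []  # 0-based inclusive 8mer/7mer-m8 spans

    for j in _find_all(seq, core):
        left = seq[j - 1] if j > 0 else None
        right = seq[j + 6] if j + 6 < len(seq) else None
        has_m8 = left == m8c
        has_a1 = right == "A"
        if has_m8 and has_a1:
            s0, e0, site_type = j - 1, j + 6, "8mer"
        elif has_m8:
            s0, e0, site_type = j - 1, j + 5, "7mer-m8"
        elif has_a1:
            s0, e0, site_type = j, j + 6, "7mer-A1"
        else:
            s0, e0, site_type = j, j + 5, "6mer"
        if site_type in ("8mer", "7mer-m8"):
            strong_spans.append((s0, e0))
        matches.append(
            SiteMatch(transcript_id, s0 + 1, e0 + 1, site_type, seq[s0 : e0 + 1])
        )

    for k in _find_all(seq, sites.site_offset6mer):
        if any(s <= k and k + 5 <= e for s, e in strong_spans):
            continue
        matches.append(
            SiteMatch(transcript_id, k + 1, k + 6, "offset-6mer", seq[k : k + 6])
        )

    matches.sort(key=lambda m: (m.start, _SITE_RANK[m.site_type]))
    # one report per (start, site_type)
    seen: set[tuple[int, str]] = set()
    deduped = []
    for m in matches:
        key = (m.start, m.site_type)
        if key not in seen:
            seen.add(key)
            deduped.append(m)
    return deduped


_COUNT_COLUMNS = {
    "8mer": "n_8mer",
    "7mer-m8": "n_7mer_m8",
    "7mer-A1": "n_7mer_A1",
    "offset-6mer": "n_offset_6mer",
    "6mer": "n_6mer",
}


def classify_transcripts(
    fasta_path: str | Path | Iterable[tuple[str, str]], sites: SeedSiteSet
) -> pd.DataFrame:
    """Scan every record of a FASTA file and tabulate per-transcript sites.

    Accepts a FASTA path or an iterable of ``(transcript_id, sequence)``
    pairs.  Returns one row per record with ``has_site`` and per-site-type
    counts; row order follows record order.
    """
    if isinstance(fasta_path, (str, Path)):
        from mirkit.io import read_fasta

        records = read_fasta(fasta_path)
    else:
        records = list(fasta_path)
        ids = [r[0] for r in records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate transcript ids: {', '.join(dupes)}")

    rows = []
    for transcript_id, seq in records:
        found = scan_transcript(transcript_id, seq, sites)
        counts = Counter(m.site_type for m in found)
        row = {"transcript_id": transcript_id, "has_site": bool(found)}
        for site_type, col in _COUNT_COLUMNS.items():
            row[col] = counts.get(site_type, 0)
        row["n_sites"] = len(found)
        rows.append(row)
    columns = ["transcript_id", "has_site", *_COUNT_COLUMNS.values(), "n_sites"]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class SitePrevalenceSummary:
    """Prevalence of predicted sites within one transcript group."""

    group: str
    n_transcripts: int
    n_with_site: int
    per_type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValidationError(f"group {self.group!r}: n_transcripts must be >= 1")
        if not 0 <= self.n_with_site <= self.n_transcripts:
            raise ValidationError(
                f"group {self.group!r}: n_with_site must lie in "
                f"[0, {self.n_transcripts}]"
            )

    @property
    def fraction(self) -> float:
        return self.n_with_site / self.n_transcripts

    @classmethod
    def from_table(cls, group: str, table: pd.DataFrame) -> "SitePrevalenceSummary":
        per_type = {
            t: int((table[c] > 0).sum()) for t, c in _COUNT_COLUMNS.items()
        }
        return cls(
            group=group,
            n_transcripts=len(table),
            n_with_site=int(table["has_site"].sum()),
            per_type_counts=per_type,
        )


def compare_site_prevalence(
    group_a: SitePrevalenceSummary, group_b: SitePrevalenceSummary
) -> dict:
    """Two-sided Fisher's exact test of site prevalence between two groups.

    The 2×2 table is [with-site, without-site] × [group A, group B].  The
    odds ratio is the sample cross-product ratio; with a zero cell it is
    reported as ``inf``/``0``/``nan`` and flagged.
    """
    a = group_a.n_with_site
    b = group_a.n_transcripts - group_a.n_with_site
    c = group_b.n_with_site
    d = group_b.n_transcripts - group_b.n_with_site
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency counts must be non-negative")
    _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    degenerate = 0 in (a, b, c, d)
    if b * c == 0:
        odds_ratio = float("nan") if a * d == 0 else float("inf")
    else:
        odds_ratio = (a * d) / (b * c)
    return {
        "odds_ratio": odds_ratio,
        "p_value": float(p_value),
        "odds_ratio_degenerate": degenerate,
        "table": ((a, b), (c, d)),
    }
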