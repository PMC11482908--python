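"""Seeded synthetic fixtures with ground truth for every pipeline stage.

The study this toolkit supports published summary tables but no raw data,
so every stage ships a generator that emulates the statistical structure
its analysis assumes, with the truth recorded alongside:

* transcripts with planted seed sites of known type and position, on a
  background guaranteed to contain no accidental site (the 6mer core and
  the offset-6mer string are rejection-sampled out of the background and
  every assembled transcript is verified by naive string search);
* a genome annotation with miRNA genes planted in known contexts;
* differential-expression tables realising configured dysregulated /
  down / lncRNA fractions by deterministic allocation (exact counts, not
  sampled);
* Ct tables with Gaussian replicate noise around configured true amplicon
  ratios or fold changes.

All generators take a :class:`numpy.random.Generator` (or an integer
seed); repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirkit.errors import ValidationError
from mirkit.locus_context import DEFAULT_THRESHOLD_BP, GeneFeature
from mirkit.seed_sites import (
    SITE_TYPES,
    MatureMiRNA,
    SeedSiteSet,
    derive_site_sequences,
)

logger = logging.getLogger(__name__)

#: Predominant mature species at the locus this toolkit was built around.
MIR317_MATURE = MatureMiRNA("miR-317-3p", "UGAACACAGUGCUAAAUGAAAGA")

_BASES = np.array(list("ACGU"))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Default study conditions for all generators.

    Transcript defaults mirror the dysregulated-lncRNA cohort that was
    manually curated (192 transcripts, 56 with sites); annotation defaults
    mirror the genome-wide miRNA survey (264 miRNA genes, 118 intronic,
    46 putatively co-transcribed); DE defaults mirror the testis RNA-seq
    summary (13232 detected, 1844 dysregulated, 59.1% down); Ct defaults
    mirror the published tissue ratios with triplicate reactions.
    """

    rng_seed: int = 0
    # transcripts
    n_transcripts: int = 192
    transcript_length: tuple[int, int] = (300, 2000)
    gc_fraction: float = 0.45
    site_counts: Mapping[str, int] = field(
        default_factory=lambda: {"8mer": 12, "7mer-m8": 10, "7mer-A1": 12, "offset-6mer": 10, "6mer": 12}
    )
    # annotation
    n_mirna_genes: int = 264
    context_mix: Mapping[str, int] = field(
        default_factory=lambda: {
            "intronic": 118,
            "exonic": 50,
            "intergenic": 50,
            "co_transcribed_downstream": 23,
            "co_transcribed_upstream": 23,
        }
    )
    threshold_bp: int = DEFAULT_THRESHOLD_BP
    # differential expression
    n_genes: int = 13232
    n_dysregulated: int = 1844
    down_fraction: float = 0.591
    n_lncrna_dysregulated: int = 192
    lncrna_up_fraction: float = 140 / 192
    log2fc_mean: float = 0.7
    log2fc_sd: float = 0.5
    # qPCR
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    n_samples: int = 6
    true_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"head": 52.0, "testis": 8.5, "testis_slow_polII": 15.3}
    )

    def __post_init__(self) -> None:
        for name, frac in (
            ("gc_fraction", self.gc_fraction),
            ("down_fraction", self.down_fraction),
            ("lncrna_up_fraction", self.lncrna_up_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if any(v < 0 for v in self.site_counts.values()):
            raise ValidationError("site counts must be non-negative")


def _allocate(n: int, fraction: float, what: str) -> int:
    """Deterministic nearest-integer allocation of ``fraction`` of ``n``."""
    exact = fraction * n
    k = int(round(exact))
    if abs(exact - k) > 1e-9:
        logger.info("%s: %.3f·%d is non-integer; allocating %d", what, fraction, n, k)
    return k


# ---------------------------------------------------------------------------
# transcripts with planted sites
# ---------------------------------------------------------------------------


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _count_occurrences(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def _expected_motif_positions(
    planted: Sequence[tuple[str, int]], sites: SeedSiteSet
) -> tuple[set[int], set[int]]:
    """0-based core and offset-6mer occurrence positions implied by plants.

    ``planted`` holds (site_type, 0-based site start).  Core-bearing sites
    carry the core at offset 1 (8mer, 7mer-m8) or 0 (7mer-A1, 6mer); 8mer
    and 7mer-m8 sites additionally embed one offset-6mer occurrence at
    their start, as does a planted offset-6mer itself.
    """
    core_at: set[int] = set()
    offset_at: set[int] = set()
    for site_type, s in planted:
        if site_type in ("8mer", "7mer-m8"):
            core_at.add(s + 1)
            offset_at.add(s)
        elif site_type in ("7mer-A1", "6mer"):
            core_at.add(s)
        elif site_type == "offset-6mer":
            offset_at.add(s)
        else:  # pragma: no cover
            raise ValidationError(f"unknown site type {site_type!r}")
    # degenerate seeds can make the two strings identical
    if sites.site_offset6mer == sites.site_6mer:
        core_at |= offset_at
        offset_at = set(core_at)
    return core_at, offset_at


def _verify_transcript(
    seq: str, planted: Sequence[tuple[str, int]], sites: SeedSiteSet
) -> bool:
    """Naive-string-search check that a transcript carries exactly its plants."""
    exp_core, exp_offset = _expected_motif_positions(planted, sites)
    if set(_count_occurrences(seq, sites.site_6mer)) != exp_core:
        return False
    if set(_count_occurrences(seq, sites.site_offset6mer)) != exp_offset:
        return False
    m8c, core = sites.m8_complement, sites.site_6mer
    for site_type, s in planted:
        if site_type == "7mer-m8":
            j = s + 1
        elif site_type in ("7mer-A1", "6mer"):
            j = s
        else:
            continue
        left = seq[j - 1] if j > 0 else None
        right = seq[j + 6] if j + 6 < len(seq) else None
        has_m8, has_a1 = left == m8c, right == "A"
        if site_type == "7mer-m8" and has_a1:
            return False
        if site_type == "7mer-A1" and has_m8:
            return False
        if site_type == "6mer" and (has_m8 or has_a1):
            return False
    return True


def _plant_one(
    rng: np.random.Generator,
    length: int,
    gc: float,
    site_type: str | None,
    sites: SeedSiteSet,
    max_tries: int = 200,
) -> tuple[str, int | None]:
    """One transcript, optionally with a single planted site; returns
    (sequence, 0-based site start or None)."""
    site_seq = sites.site(site_type) if site_type else None
    if site_seq is not None and len(site_seq) > length:
        raise ValidationError(
            f"site {site_type} ({len(site_seq)} nt) does not fit in a "
            f"{length} nt transcript"
        )
    for _ in range(max_tries):
        if site_seq is None:
            seq = _random_background(rng, length, gc)
            if _verify_transcript(seq, [], sites):
                return seq, None
            continue
        pos = int(rng.integers(1, length - len(site_seq)))  # keep both flanks inside
        bg = _random_background(rng, length - len(site_seq), gc)
        seq = bg[:pos] + site_seq + bg[pos:]
        if _verify_transcript(seq, [(site_type, pos)], sites):
            return seq, pos
    raise ValidationError(
        f"could not assemble a clean transcript of length {length} "
        f"(site {site_type}) in {max_tries} tries"
    )


def make_transcripts(
    config: SimulationConfig | None = None,
    rng: int | np.random.Generator | None = None,
    mirna: MatureMiRNA = MIR317_MATURE,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate transcripts with planted sites and their truth table.

    The first ``sum(site_counts.values())`` transcripts carry exactly one
    planted site each (types in ``SITE_TYPES`` order); the rest are clean
    background.  Returns ``(records, truth)`` where records are
    ``(transcript_id, sequence)`` pairs and the truth table has one row per
    transcript (``site_type``/``start``/``end`` are '.' and 0 for clean
    transcripts; coordinates are 1-based inclusive).
    """
    config = config or SimulationConfig()
    gen = _rng(config.rng_seed if rng is None else rng)
    sites = derive_site_sequences(mirna)
    n_planted = sum(config.site_counts.values())
    if n_planted > config.n_transcripts:
        raise ValidationError("more planted sites than transcripts")
    lo, hi = config.transcript_length
    plan: list[str | None] = []
    for site_type in SITE_TYPES:
        plan.extend([site_type] * config.site_counts.get(site_type, 0))
    plan.extend([None] * (config.n_transcripts - n_planted))

    records, truth_rows = [], []
    for i, site_type in enumerate(plan):
        tid = f"tx{i + 1:04d}"
        length = int(gen.integers(lo, hi + 1))
        seq, pos = _plant_one(gen, length, config.gc_fraction, site_type, sites)
        records.append((tid, seq))
        if site_type is None:
            truth_rows.append(
                {"transcript_id": tid, "site_type": ".", "start": 0, "end": 0}
            )
        else:
            site_len = len(sites.site(site_type))
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "site_type": site_type,
                    "start": pos + 1,
                    "end": pos + site_len,
                }
            )
    return records, pd.DataFrame(truth_rows)


def make_lncrna_cohort(
    rng: int | np.random.Generator = 0,
    n_up: int = 140,
    n_up_with_site: int = 38,
    n_down: int = 52,
    n_down_with_site: int = 18,
    mirna: MatureMiRNA = MIR317_MATURE,
    length: tuple[int, int] = (300, 2000),
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """A dysregulated-lncRNA cohort with configured site prevalence.

    Defaults reproduce the curated testis cohort: 140 upregulated lncRNAs
    of which 38 carry a site, 52 downregulated of which 18 do (56/192
    overall).  Site types cycle through the five classes.  Returns
    ``(records, truth)``; truth columns are ``transcript_id``,
    ``direction`` and ``has_site``.
    """
    gen = _rng(rng)
    sites = derive_site_sequences(mirna)
    records, rows = [], []
    idx = 0
    for direction, n, n_site in (("up", n_up, n_up_with_site), ("down", n_down, n_down_with_site)):
        if n_site > n:
            raise ValidationError("n_with_site cannot exceed the group size")
        for j in range(n):
            idx += 1
            tid = f"lnc_{direction}_{idx:04d}"
            site_type = SITE_TYPES[j % len(SITE_TYPES)] if j < n_site else None
            tlen = int(gen.integers(length[0], length[1] + 1))
            seq, _ = _plant_one(gen, tlen, 0.45, site_type, sites)
            records.append((tid, seq))
            rows.append(
                {
                    "transcript_id": tid,
                    "direction": direction,
                    "has_site": site_type is not None,
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome annotation with planted miRNA contexts
# ---------------------------------------------------------------------------

_BLOCK = 20_000  # bp reserved per planted miRNA locus


def make_annotation(
    config: SimulationConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[list[GeneFeature], pd.DataFrame]:
    """Plant miRNA genes in known genomic contexts on one synthetic chromosome.

    Each miRNA gets its own 20 kb block, so cross-block distances exceed
    any sensible proximity threshold.  Co-transcribed neighbours are placed
    at a gap drawn uniformly from [0, threshold_bp]; the truth table
    records category, planted neighbour gap and host/neighbour id.
    """
    config = config or SimulationConfig()
    gen = _rng(config.rng_seed if rng is None else rng)
    mix = dict(config.context_mix)
    unknown = set(mix) - {
        "intronic",
        "exonic",
        "intergenic",
        "co_transcribed_downstream",
        "co_transcribed_upstream",
    }
    if unknown:
        raise ValidationError(f"unknown context categories: {sorted(unknown)}")
    if config.threshold_bp + 200 > _BLOCK // 2:
        raise ValidationError("threshold too large for the block layout")

    features: list[GeneFeature] = []
    truth_rows = []
    plan: list[str] = []
    for cat in ("intronic", "exonic", "intergenic", "co_transcribed_downstream", "co_transcribed_upstream"):
        plan.extend([cat] * mix.get(cat, 0))
    chrom = "chrSim"
    for i, category in enumerate(plan):
        b = i * _BLOCK
        mid = f"mir{i + 1:04d}"
        host_id = None
        distance = 0
        if category in ("intronic", "exonic"):
            host_id = f"host{i + 1:04d}"
            tx_id = host_id + ".t1"
            features.append(
                GeneFeature(host_id, "gene", chrom, "+", b + 1000, b + 9000, biotype="coding")
            )
            features.append(
                GeneFeature(tx_id, "transcript", chrom, "+", b + 1000, b + 9000, parent_id=host_id, biotype="coding")
            )
            features.append(
                GeneFeature(tx_id + ".e1", "exon", chrom, "+", b + 1000, b + 2000, parent_id=tx_id)
            )
            features.append(
                GeneFeature(tx_id + ".e2", "exon", chrom, "+", b + 8000, b + 9000, parent_id=tx_id)
            )
            if category == "intronic":
                m_start = b + 4000
            else:
                m_start = b + 1200  # inside exon 1
            host_id = tx_id
        elif category == "intergenic":
            m_start = b + 10_000
        else:
            host_id = f"nbr{i + 1:04d}"
            distance = int(gen.integers(0, config.threshold_bp + 1))
            if category == "co_transcribed_downstream":
                # neighbour ends `distance` bp 5' of the miRNA start
                n_end = b + 6000
                m_start = n_end + distance + 1
                features.append(
                    GeneFeature(host_id, "gene", chrom, "+", b + 2000, n_end, biotype="ncRNA")
                )
            else:
                m_start = b + 6000
                n_start = m_start + 90 + distance + 1
                features.append(
                    GeneFeature(host_id, "gene", chrom, "+", n_start, n_start + 3000, biotype="ncRNA")
                )
        features.append(
            GeneFeature(mid, "miRNA_gene", chrom, "+", m_start, m_start + 90, biotype="miRNA")
        )
        truth_rows.append(
            {
                "mirna_id": mid,
                "category": category,
                "host_or_neighbor_id": host_id if host_id else ".",
                "distance_bp": distance,
            }
        )
    return features, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


def make_de_table(
    config: SimulationConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A DE table realising the configured fractions by exact allocation.

    Dysregulated genes get ``padj`` drawn below 0.05 and |log2fc| =
    0.05 + |N(log2fc_mean, log2fc_sd)| with the allocated sign;
    non-dysregulated genes get ``padj`` in [0.05, 1) and small fold
    changes.  lncRNA dysregulation has its own up-fraction so cohorts like
    the testis lncRNAs (140 up / 52 down) are reproduced exactly.
    """
    config = config or SimulationConfig()
    gen = _rng(config.rng_seed if rng is None else rng)
    n, n_dys = config.n_genes, config.n_dysregulated
    if n_dys > n:
        raise ValidationError("n_dysregulated cannot exceed n_genes")
    n_lnc_dys = config.n_lncrna_dysregulated
    if n_lnc_dys > n_dys:
        raise ValidationError("lncRNA dysregulated count exceeds total dysregulated")
    n_lnc_up = _allocate(n_lnc_dys, config.lncrna_up_fraction, "lncRNA up")
    n_down_total = _allocate(n_dys, config.down_fraction, "down")
    n_lnc_down = n_lnc_dys - n_lnc_up
    n_coding_down = n_down_total - n_lnc_down
    n_coding_dys = n_dys - n_lnc_dys
    if not 0 <= n_coding_down <= n_coding_dys:
        raise ValidationError("down/lncRNA fractions are mutually infeasible")

    directions = (
        ["up"] * n_lnc_up
        + ["down"] * n_lnc_down
        + ["down"] * n_coding_down
        + ["up"] * (n_coding_dys - n_coding_down)
        + [None] * (n - n_dys)
    )
    biotypes = (
        ["lncRNA"] * n_lnc_dys
        + ["coding"] * (n - n_lnc_dys)
    )
    rows = []
    for i, (direction, biotype) in enumerate(zip(directions, biotypes)):
        gid = f"FBgnS{i + 1:07d}"
        if direction is None:
            log2fc = float(gen.normal(0.0, 0.1))
            padj = float(gen.uniform(0.05, 1.0))
        else:
            mag = 0.05 + abs(float(gen.normal(config.log2fc_mean, config.log2fc_sd)))
            log2fc = mag if direction == "up" else -mag
            padj = float(10.0 ** -gen.uniform(1.31, 12.0))  # < 0.049
        rows.append(
            {
                "gene_id": gid,
                "gene_name": gid,
                "log2fc": round(log2fc, 4),
                "padj": padj,
                "biotype": biotype,
            }
        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "gene_id": table["gene_id"],
            "biotype": biotypes,
            "dysregulated": [d is not None for d in directions],
            "direction": [d if d else "." for d in directions],
        }
    )
    return table, truth


def make_prediction_lists(
    rng: int | np.random.Generator = 0,
    sizes: Mapping[str, int] | None = None,
    n_exactly_two: int = 74,
    n_exactly_three: int = 2,
    gene_pool: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Three prediction lists with a controlled overlap structure.

    Defaults construct lists of sizes 975/102/31 with 74 genes in exactly
    two lists and 2 in all three, giving a union of 1030 with 76
    multi-source genes.  Overlapping genes are shared between the two
    largest lists.  If ``gene_pool`` is given, ids are drawn from it
    (without replacement); otherwise synthetic ids are minted.
    """
    gen = _rng(rng)
    sizes = dict(sizes or {"microRNA.org": 975, "TargetScanFly": 102, "MinoTar": 31})
    if len(sizes) != 3:
        raise ValidationError("exactly three source lists are expected")
    labels = sorted(sizes, key=lambda k: -sizes[k])
    n_total = sum(sizes.values()) - n_exactly_two - 2 * n_exactly_three
    if gene_pool is None:
        pool = [f"FBgnP{i + 1:07d}" for i in range(n_total)]
    else:
        pool = list(gene_pool)
        if len(pool) < n_total:
            raise ValidationError("gene pool smaller than the union size")
        idx = gen.choice(len(pool), size=n_total, replace=False)
        pool = [pool[int(i)] for i in idx]
    it = iter(pool)
    triple = [next(it) for _ in range(n_exactly_three)]
    double = [next(it) for _ in range(n_exactly_two)]
    lists = {lab: set(triple) for lab in labels}
    lists[labels[0]].update(double)
    lists[labels[1]].update(double)
    for lab in labels:
        shortfall = sizes[lab] - len(lists[lab])
        if shortfall < 0:
            raise ValidationError(
                f"list {lab!r} too small for the requested overlap structure"
            )
        lists[lab].update(next(it) for _ in range(shortfall))
    return lists


def make_target_study(
    config: SimulationConfig | None = None,
    rng: int | np.random.Generator | None = None,
    n_detected_predictions: int = 919,
    n_dysregulated_predictions: int = 142,
    n_down_predictions: int = 88,
    n_strong_up_predictions: int = 15,
    min_log2fc: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """A DE table plus prediction lists with a configured intersection.

    Defaults emulate the testis target screen: of 1030 predicted targets,
    919 are detected in the DE table, 142 of those are dysregulated (88
    down, 54 up), and 15 of the upregulated exceed a log2FC of 0.5.
    Returns ``(de_table, prediction_lists)``; prediction genes are drawn
    from the appropriate truth strata of the generated DE table, topped up
    with ids absent from it.
    """
    config = config or SimulationConfig()
    gen = _rng(config.rng_seed if rng is None else rng)
    de_table, truth = make_de_table(config, rng=gen)
    merged = de_table.merge(truth[["gene_id", "direction"]], on="gene_id")
    up = merged[merged["direction"] == "up"]
    strong_up = list(up.loc[up["log2fc"] > min_log2fc, "gene_id"])
    weak_up = list(up.loc[up["log2fc"] <= min_log2fc, "gene_id"])
    down = list(merged.loc[merged["direction"] == "down", "gene_id"])
    stable = list(merged.loc[merged["direction"] == ".", "gene_id"])
    n_up_pred = n_dysregulated_predictions - n_down_predictions
    n_weak_up = n_up_pred - n_strong_up_predictions
    n_stable = n_detected_predictions - n_dysregulated_predictions
    for pool, need, what in (
        (strong_up, n_strong_up_predictions, "strong upregulated"),
        (weak_up, n_weak_up, "weakly upregulated"),
        (down, n_down_predictions, "downregulated"),
        (stable, n_stable, "non-dysregulated"),
    ):
        if len(pool) < need:
            raise ValidationError(
                f"DE table has only {len(pool)} {what} genes; {need} required"
            )

    def pick(pool: list[str], k: int) -> list[str]:
        idx = gen.choice(len(pool), size=k, replace=False)
        return [pool[int(i)] for i in sorted(idx)]

    chosen = (
        pick(strong_up, n_strong_up_predictions)
        + pick(weak_up, n_weak_up)
        + pick(down, n_down_predictions)
        + pick(stable, n_stable)
    )
    sizes = dict(
        {"microRNA.org": 975, "TargetScanFly": 102, "MinoTar": 31}
    )
    n_union = sum(sizes.values()) - 74 - 2 * 2
    n_absent = n_union - n_detected_predictions
    chosen += [f"FBgnU{i + 1:07d}" for i in range(n_absent)]  # not in the DE table
    lists = make_prediction_lists(rng=gen, sizes=sizes, gene_pool=chosen)
    return de_table, lists


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def make_ct_table(
    config: SimulationConfig | None = None,
    rng: int | np.random.Generator | None = None,
    amplicon_a: str = "lncRNA_body",
    amplicon_b: str = "pre_miRNA",
    base_ct: float = 20.0,
    between_sample_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct measurements around configured true amplicon ratios.

    Per condition, ``n_samples`` biological samples each get a base Ct for
    amplicon a (base_ct + between-sample jitter); amplicon b sits
    ``log2(true ratio)`` cycles higher, so ``2^(Ct_b − Ct_a)`` recovers the
    a : b ratio.  Replicate Ct values add Gaussian noise of sd
    ``ct_noise_sd``.  Returns ``(measurements, truth)``.
    """
    config = config or SimulationConfig()
    gen = _rng(config.rng_seed if rng is None else rng)
    rows, truth_rows = [], []
    for condition in sorted(config.true_ratios):
        ratio = float(config.true_ratios[condition])
        if ratio <= 0:
            raise ValidationError("true ratios must be positive")
        truth_rows.append({"condition": condition, "true_ratio": ratio})
        for s in range(config.n_samples):
            sample_id = f"{condition}_s{s + 1}"
            ct_a = base_ct + float(gen.normal(0.0, between_sample_sd))
            ct_b = ct_a + math.log2(ratio)
            for amplicon, true_ct in ((amplicon_a, ct_a), (amplicon_b, ct_b)):
                for r in range(config.n_replicates):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": condition,
                            "amplicon": amplicon,
                            "replicate": r + 1,
                            "ct": round(true_ct + float(gen.normal(0.0, config.ct_noise_sd)), 4),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def make_ddct_table(
    rng: int | np.random.Generator = 0,
    true_fold_changes: Mapping[str, float] | None = None,
    reference_condition: str = "control",
    target: str = "target_gene",
    control_amplicon: str = "aTub84B",
    n_samples: int = 3,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.2,
    base_ct: float = 22.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct measurements around configured true fold changes vs a reference.

    The endogenous-control amplicon has the same true Ct everywhere; the
    target amplicon shifts by ``−log2(FC)`` cycles in each non-reference
    condition.  Defaults emulate a triplicated two-genotype experiment.
    """
    gen = _rng(rng)
    fcs = dict(true_fold_changes or {"mutant": 2.0})
    fcs[reference_condition] = 1.0
    rows, truth_rows = [], []
    for condition in sorted(fcs):
        fc = float(fcs[condition])
        if fc <= 0:
            raise ValidationError("fold changes must be positive")
        truth_rows.append({"condition": condition, "true_fold_change": fc})
        for s in range(n_samples):
            sample_id = f"{condition}_s{s + 1}"
            jitter = float(gen.normal(0.0, 0.3))
            ct_control = base_ct + jitter
            ct_target = base_ct + 4.0 + jitter - math.log2(fc)
            for amplicon, true_ct in ((target, ct_target), (control_amplicon, ct_control)):
                for r in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": condition,
                            "amplicon": amplicon,
                            "replicate": r + 1,
                            "ct": round(true_ct + float(gen.normal(0.0, ct_noise_sd)), 4),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
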