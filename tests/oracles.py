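"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, exact fractions,
exhaustive pair testing) and shares no code with the package internals.
"""

from fractions import Fraction
from math import comb

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def naive_sites(mature: str) -> dict[str, str]:
    """Per-base complementation + reversal, straight from the definitions."""
    m = mature.upper().replace("T", "U")

    def rc(s):
        out = []
        for b in s:
            out.append(_COMP[b])
        out.reverse()
        return "".join(out)

    return {
        "seed": m[1:7],
        "8mer": rc(m[1:8]) + "A",
        "7mer-m8": rc(m[1:8]),
        "7mer-A1": rc(m[1:7]) + "A",
        "offset-6mer": rc(m[2:8]),
        "6mer": rc(m[1:7]),
    }


def naive_scan(seq: str, mature: str) -> list[tuple[int, int, str]]:
    """Search each of the five site strings independently, then apply the
    most-specific-wins precedence per core occurrence and the containment
    rule for offset-6mers.  Returns 1-based (start, end, type) tuples."""
    seq = seq.upper().replace("T", "U")
    sites = naive_sites(mature)
    occ = {}
    for t in ("8mer", "7mer-m8", "7mer-A1", "offset-6mer", "6mer"):
        s = sites[t]
        occ[t] = [i for i in range(len(seq) - len(s) + 1) if seq[i : i + len(s)] == s]
    reported = []
    strong = []
    for j in occ["6mer"]:  # each core occurrence, classified once
        if j - 1 in occ["8mer"]:
            reported.append((j - 1, j + 6, "8mer"))
            strong.append((j - 1, j + 6))
        elif j - 1 in occ["7mer-m8"]:
            reported.append((j - 1, j + 5, "7mer-m8"))
            strong.append((j - 1, j + 5))
        elif j in occ["7mer-A1"]:
            reported.append((j, j + 6, "7mer-A1"))
        else:
            reported.append((j, j + 5, "6mer"))
    for k in occ["offset-6mer"]:
        if not any(s <= k and k + 5 <= e for s, e in strong):
            reported.append((k, k + 5, "offset-6mer"))
    out = sorted({(s + 1, e + 1, t) for s, e, t in reported})
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive enumeration over all tables
    with the observed margins, using exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(table with first cell = x)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return total


def loop_ddct(rows, target, control, reference):
    """FC = 2^-ddCt computed with explicit loops over a list of dicts with
    keys sample_id, condition, amplicon, ct."""
    samples = {}
    for r in rows:
        samples.setdefault(r["sample_id"], {"condition": r["condition"], "ct": {}})
        samples[r["sample_id"]]["ct"].setdefault(r["amplicon"], []).append(r["ct"])
    dct = {}
    for sid, info in samples.items():
        mt = sum(info["ct"][target]) / len(info["ct"][target])
        mc = sum(info["ct"][control]) / len(info["ct"][control])
        dct[sid] = mt - mc
    ref = [dct[s] for s, i in samples.items() if i["condition"] == reference]
    ref_mean = sum(ref) / len(ref)
    return {sid: 2.0 ** -(d - ref_mean) for sid, d in dct.items()}


def pooled_t(xs, ys):
    """Textbook equal-variance two-sample t statistic."""
    nx, ny = len(xs), len(ys)
    mx, my = sum(xs) / nx, sum(ys) / ny
    ssx = sum((x - mx) ** 2 for x in xs)
    ssy = sum((y - my) ** 2 for y in ys)
    sp2 = (ssx + ssy) / (nx + ny - 2)
    return (mx - my) / (sp2 * (1 / nx + 1 / ny)) ** 0.5


def brute_force_context(mirna, features, threshold):
    """Exhaustive (miRNA, feature) pair testing version of the genomic
    context rules, for small annotations.  ``mirna``/``features`` are
    GeneFeature-like objects (attribute access only)."""

    def is_mir(f):
        return f.feature_type == "miRNA_gene" or f.biotype == "miRNA"

    def overlaps(x, y):
        return x.chrom == y.chrom and x.start <= y.end and y.start <= x.end

    by_id = {f.feature_id: f for f in features}

    def lineage_of(fid):
        ids = {fid}
        changed = True
        while changed:
            changed = False
            for f in features:
                if f.parent_id in ids and f.feature_id not in ids:
                    ids.add(f.feature_id)
                    changed = True
                if f.feature_id in ids and f.parent_id and f.parent_id not in ids:
                    ids.add(f.parent_id)
                    changed = True
        return ids

    excluded = lineage_of(mirna.feature_id)

    # candidate hosts: non-miRNA transcripts, or childless non-miRNA genes
    exonic, intronic = [], []
    for h in features:
        if h.feature_id in excluded or is_mir(h):
            continue
        if h.feature_type in ("transcript", "mRNA", "ncRNA_transcript"):
            parent = by_id.get(h.parent_id)
            if parent is not None and is_mir(parent):
                continue
        elif h.feature_type == "gene":
            if any(
                c.parent_id == h.feature_id
                and c.feature_type in ("transcript", "mRNA", "ncRNA_transcript")
                for c in features
            ):
                continue
        else:
            continue
        exons = [
            e
            for e in features
            if e.feature_type == "exon" and e.parent_id == h.feature_id
        ]
        if any(overlaps(e, mirna) for e in exons):
            exonic.append(h)
        elif (
            h.chrom == mirna.chrom
            and h.start <= mirna.start
            and mirna.end <= h.end
        ):
            intronic.append(h)
    for cat, hosts in (("exonic", exonic), ("intronic", intronic)):
        if hosts:
            host = sorted(hosts, key=lambda h: (h.end - h.start, h.feature_id))[0]
            return (cat, host.feature_id, 0, host.strand == mirna.strand)

    def gap(g):
        if overlaps(g, mirna):
            return 0
        if g.end < mirna.start:
            return mirna.start - g.end - 1
        return g.start - mirna.end - 1

    best = None  # (gap, pref, gene)
    for g in features:
        if (
            g.feature_type not in ("gene", "miRNA_gene")
            or g.feature_id in excluded
            or is_mir(g)
            or g.chrom != mirna.chrom
            or g.strand != mirna.strand
            or overlaps(g, mirna)
        ):
            continue
        d = gap(g)
        if d > threshold:
            continue
        is_5prime = (g.end < mirna.start) if mirna.strand == "+" else (g.start > mirna.end)
        cat = "co_transcribed_downstream" if is_5prime else "co_transcribed_upstream"
        key = (d, 0 if is_5prime else 1, g.feature_id)
        if best is None or key < best[0]:
            best = (key, cat, g)
    if best is not None:
        return (best[1], best[2].feature_id, best[0][0], True)

    near = None
    for g in features:
        if (
            g.feature_type not in ("gene", "miRNA_gene")
            or g.feature_id in excluded
            or is_mir(g)
            or g.chrom != mirna.chrom
        ):
            continue
        key = (gap(g), g.feature_id)
        if near is None or key < near[0]:
            near = (key, g)
    if near is None:
        return ("intergenic", None, 0, False)
    return ("intergenic", near[1].feature_id, near[0][0], near[1].strand == mirna.strand)
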