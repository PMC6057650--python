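"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementations they check: the
off-target oracle tests every substring, strand and bulge placement with
explicit string alignments; the interval oracle paints a boolean mask; the
rank-sum oracle enumerates every group assignment.
"""

from __future__ import annotations

import itertools

from trioaudit.guide_offtarget import IUPAC
from trioaudit.io_formats import revcomp


def _pam_match(s: str, pattern: str) -> bool:
    return len(s) == len(pattern) and all(
        base in IUPAC[sym] for base, sym in zip(s, pattern)
    )


def brute_force_offtargets(genome, guide, max_mm, max_mm_bulge, allow_bulge):
    """All (chrom, start, end, strand, bulge) -> min mismatches, by testing
    every window, every strand, and every explicit bulge placement."""
    sites: dict[tuple, int] = {}
    proto = guide.protospacer
    for chrom, fwd in genome.sequences.items():
        n = len(fwd)
        for strand, s in (("+", fwd), ("-", revcomp(fwd))):

            def to_genome(i: int, span: int) -> int:
                return i if strand == "+" else n - i - span

            for i in range(n - 22):
                w = s[i : i + 23]
                if "N" in w:
                    continue
                if not any(_pam_match(w[20:], p) for p in guide.pam_patterns):
                    continue
                mm = sum(a != b for a, b in zip(w[:20], proto))
                if mm <= max_mm:
                    g = to_genome(i, 23)
                    key = (chrom, g, g + 23, strand, "none")
                    sites[key] = min(sites.get(key, 99), mm)
            if not allow_bulge:
                continue
            # DNA bulge: drop one interior base of a 21-base genomic stretch
            for i in range(n - 23):
                w = s[i : i + 24]
                if "N" in w:
                    continue
                if not any(_pam_match(w[21:], p) for p in guide.pam_patterns):
                    continue
                best = 99
                for k in range(1, 20):
                    aligned = w[:k] + w[k + 1 : 21]
                    best = min(best, sum(a != b for a, b in zip(aligned, proto)))
                if best <= max_mm_bulge:
                    g = to_genome(i, 24)
                    key = (chrom, g, g + 24, strand, "dna")
                    sites[key] = min(sites.get(key, 99), best)
            # RNA bulge: drop one interior guide base, 19-base genomic stretch
            for i in range(n - 21):
                w = s[i : i + 22]
                if "N" in w:
                    continue
                if not any(_pam_match(w[19:], p) for p in guide.pam_patterns):
                    continue
                best = 99
                for k in range(1, 19):
                    gapped = proto[:k] + proto[k + 1 :]
                    best = min(best, sum(a != b for a, b in zip(w[:19], gapped)))
                if best <= max_mm_bulge:
                    g = to_genome(i, 22)
                    key = (chrom, g, g + 22, strand, "rna")
                    sites[key] = min(sites.get(key, 99), best)
    return sites


def enumerated_wilcoxon_p(x: list[float], y: list[float]) -> float:
    """Two-sided Wilcoxon rank-sum p by complete enumeration of all
    C(n+m, n) group assignments (no ties expected)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(x)
    w_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    center = n * len(y) / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        w = sum(combo) - n * (n + 1) / 2
        total += 1
        if abs(w - center) >= abs(w_obs - center) - 1e-9:
            extreme += 1
    return extreme / total
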