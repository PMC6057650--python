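"""CRISPR guide off-target site enumeration and variant-window intersection.

Enumerates every genomic locus where a 20-nt protospacer aligns adjacent to
a PAM with a limited number of mismatches, optionally tolerating a single
1-nt bulge:

* no bulge   — 23-base genomic span (20-nt protospacer + 3-nt PAM);
* DNA bulge  — one extra, unpaired genomic base inside the protospacer
  alignment (24-base span);
* RNA bulge  — one guide base unpaired, i.e. a genomic base skipped
  (22-base span).

Bulges are restricted to the interior of the protospacer alignment (never at
either terminus and never in the PAM), so a bulged alignment is never a
re-description of the plain 23-mer match.  The PAM is matched with IUPAC
codes on the protospacer-adjacent 3' side of the matched strand.  Spans
containing N are never matched.  Sites are deduplicated per
(chrom, span, strand, bulge class), keeping the minimum mismatch count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Genome, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class GuideSpec:
    """A 20-nt protospacer plus the PAM patterns it can use."""

    protospacer: str
    pam_patterns: tuple[str, ...] = ("NGG",)
    name: str = ""

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        if len(proto) != 20 or set(proto) - set("ACGT"):
            raise ValueError("protospacer must be 20 nt of A/C/G/T")
        object.__setattr__(self, "protospacer", proto)
        pams = tuple(p.upper() for p in self.pam_patterns)
        for p in pams:
            if len(p) != 3 or set(p) - set(IUPAC):
                raise ValueError(f"bad PAM pattern {p!r}")
        object.__setattr__(self, "pam_patterns", pams)


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic protospacer+PAM match; span is 0-based half-open on chrom."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    bulge: str  # 'none', 'dna', 'rna'
    bulge_size: int
    matched_seq: str
    is_on_target: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


_SPAN = {"none": 23, "dna": 24, "rna": 22}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, 4, dtype=np.uint8)
for base, code in _CODE.items():
    _LUT[ord(base)] = code


def _codes(seq: str) -> np.ndarray:
    return _LUT[_encode(seq)]


def _pam_ok(arr: np.ndarray, offset: int, pam_patterns: Sequence[str], n_win: int) -> np.ndarray:
    """Boolean array over window starts: PAM (at window start + offset)
    matches any pattern."""
    ok = np.zeros(n_win, dtype=bool)
    for pat in pam_patterns:
        this = np.ones(n_win, dtype=bool)
        for j, sym in enumerate(pat):
            allowed = IUPAC[sym]
            col = arr[offset + j : offset + j + n_win]
            m = np.zeros(n_win, dtype=bool)
            for b in allowed:
                m |= col == _CODE[b]
            this &= m
        ok |= this
    return ok


def _window_has_n(arr: np.ndarray, span: int, n_win: int) -> np.ndarray:
    is_n = (arr == 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    return (cum[span : span + n_win] - cum[:n_win]) > 0


def _scan_strand(
    arr: np.ndarray,
    guide: GuideSpec,
    max_mm_nobulge: int,
    max_mm_bulge: int,
    allow_bulge: bool,
) -> dict[tuple[int, str], int]:
    """Scan one strand (codes array in matched-strand orientation).

    Returns {(window_start, bulge_class): min mismatches}.
    """
    proto = _codes(guide.protospacer)
    n = arr.size
    hits: dict[tuple[int, str], int] = {}

    def record(starts: np.ndarray, mm: np.ndarray, bulge: str) -> None:
        for s, m in zip(starts.tolist(), mm.tolist()):
            key = (s, bulge)
            if key not in hits or m < hits[key]:
                hits[key] = m

    # --- no bulge: 23-base windows -------------------------------------
    span = 23
    n_win = n - span + 1
    if n_win > 0:
        mm = np.zeros(n_win, dtype=np.int16)
        for j in range(20):
            mm += arr[j : j + n_win] != proto[j]
        ok = (
            (mm <= max_mm_nobulge)
            & _pam_ok(arr, 20, guide.pam_patterns, n_win)
            & ~_window_has_n(arr, span, n_win)
        )
        idx = np.nonzero(ok)[0]
        record(idx, mm[idx], "none")

    if not allow_bulge:
        return hits

    # --- DNA bulge: 1 extra genomic base, 24-base windows ---------------
    # Guide position j pairs with genomic j for j < k and genomic j+1 for
    # j >= k, where genomic index k (1..19) is the unpaired bulge base.
    span = 24
    n_win = n - span + 1
    if n_win > 0:
        m0 = np.zeros((21, n_win), dtype=np.int16)  # cumulative prefix mm
        m1 = np.zeros((21, n_win), dtype=np.int16)  # cumulative shifted mm
        for j in range(20):
            m0[j + 1] = m0[j] + (arr[j : j + n_win] != proto[j])
            m1[j + 1] = m1[j] + (arr[j + 1 : j + 1 + n_win] != proto[j])
        pam = _pam_ok(arr, 21, guide.pam_patterns, n_win)
        no_n = ~_window_has_n(arr, span, n_win)
        best = np.full(n_win, np.iinfo(np.int16).max, dtype=np.int16)
        for k in range(1, 20):
            mm_k = m0[k] + (m1[20] - m1[k])
            np.minimum(best, mm_k, out=best)
        ok = (best <= max_mm_bulge) & pam & no_n
        idx = np.nonzero(ok)[0]
        record(idx, best[idx], "dna")

    # --- RNA bulge: 1 guide base unpaired, 22-base windows --------------
    # Guide position j pairs with genomic j for j < k and genomic j-1 for
    # j > k, where guide index k (1..18) is the unpaired guide base.
    span = 22
    n_win = n - span + 1
    if n_win > 0:
        a = np.zeros((21, n_win), dtype=np.int16)
        b = np.zeros((21, n_win), dtype=np.int16)
        for j in range(20):
            a[j + 1] = a[j] + (arr[j : j + n_win] != proto[j])
            if j >= 1:
                b[j + 1] = b[j] + (arr[j - 1 : j - 1 + n_win] != proto[j])
            else:
                b[j + 1] = b[j]
        pam = _pam_ok(arr, 19, guide.pam_patterns, n_win)
        no_n = ~_window_has_n(arr, span, n_win)
        best = np.full(n_win, np.iinfo(np.int16).max, dtype=np.int16)
        for k in range(1, 19):
            mm_k = a[k] + (b[20] - b[k + 1])
            np.minimum(best, mm_k, out=best)
        ok = (best <= max_mm_bulge) & pam & no_n
        idx = np.nonzero(ok)[0]
        record(idx, best[idx], "rna")

    return hits


def enumerate_offtargets(
    genome: Genome,
    guide: GuideSpec,
    max_mm_nobulge: int = 4,
    max_mm_bulge: int = 3,
    allow_bulge: bool = True,
) -> list[OffTargetSite]:
    """Find every candidate off-target site for ``guide`` in ``genome``.

    The perfect protospacer+PAM match (0 mismatches, no bulge) is included
    and flagged ``is_on_target``.
    """
    if genome.total_size == 0:
        raise ValueError("empty genome")
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        fwd = _scan_strand(_codes(seq), guide, max_mm_nobulge, max_mm_bulge, allow_bulge)
        for (start, bulge), mm in fwd.items():
            span = _SPAN[bulge]
            sites.append(
                OffTargetSite(
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    strand="+",
                    mismatches=mm,
                    bulge=bulge,
                    bulge_size=0 if bulge == "none" else 1,
                    matched_seq=seq[start : start + span],
                    is_on_target=(bulge == "none" and mm == 0),
                )
            )
        rc = revcomp(seq)
        rev = _scan_strand(_codes(rc), guide, max_mm_nobulge, max_mm_bulge, allow_bulge)
        for (start_rc, bulge), mm in rev.items():
            span = _SPAN[bulge]
            start = n - start_rc - span
            sites.append(
                OffTargetSite(
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    strand="-",
                    mismatches=mm,
                    bulge=bulge,
                    bulge_size=0 if bulge == "none" else 1,
                    matched_seq=rc[start_rc : start_rc + span],
                    is_on_target=(bulge == "none" and mm == 0),
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand, s.bulge))
    return sites


def window_intersect(
    sites: Sequence[OffTargetSite],
    variants: Iterable,
    window: int = 10,
) -> list[tuple[object, OffTargetSite]]:
    """Pairs (variant, site) where the variant position falls within the
    site span extended by ``window`` bases on both sides.

    ``variants`` may be any objects exposing ``chrom`` and ``pos0`` (0-based
    position); :class:`~trioaudit.dnm_calling.CandidateDNM` and
    :class:`~trioaudit.io_formats.VariantRecord` both qualify.
    """
    by_chrom: dict[str, list[OffTargetSite]] = {}
    for site in sites:
        by_chrom.setdefault(site.chrom, []).append(site)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: (s.start, s.end, s.strand, s.bulge))
        starts[chrom] = np.array([s.start for s in group])
        ends[chrom] = np.array([s.end for s in group])
    max_span = max(_SPAN.values())
    hits: list[tuple[object, OffTargetSite]] = []
    for var in variants:
        chrom = var.chrom
        if chrom not in by_chrom:
            continue
        pos = var.pos0
        st, en, group = starts[chrom], ends[chrom], by_chrom[chrom]
        lo = np.searchsorted(st, pos - window - max_span, side="left")
        hi = np.searchsorted(st, pos + window, side="right")
        for i in range(int(lo), int(hi)):
            if st[i] - window <= pos < en[i] + window:
                hits.append((var, group[i]))
    return hits


def expected_intersections(
    n_dnm: int, site_span: int, n_sites: int, genome_size: float
) -> float:
    """Expected chance intersections between candidate DNMs and windowed
    off-target sites: n_dnm * site_span * n_sites / genome_size.

    ``site_span`` here is the windowed footprint of a site (23-base span plus
    the intersection window on each side; 43 for a 10-base window).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if min(n_dnm, site_span, n_sites) < 0:
        raise ValueError("inputs must be non-negative")
    return n_dnm * site_span * n_sites / genome_size
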