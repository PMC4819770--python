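"""Design constraints for intronic smFISH oligo probe sets.

Nascent-transcript FISH uses sets of ~5 fluor-labeled 50-mers tiled over a
short stretch of an intron. The constraints screened here:

* all oligos in a set share roughly the same GC content (~55%) so they
  hybridize with similar efficiency;
* amino-modified T residues carrying the fluors must sit more than ~8
  bases apart (closer fluors quench each other), ~5 per 50-mer;
* no 20-nucleotide segment of an oligo may occur elsewhere in the genome
  (on either strand), or the probe lights up off-target sites;
* the whole set must span at most ~600 nt of the transcript (ideally
  <400 nt) so the labeled region stays smaller than the diffraction limit
  and behaves like a point source.

All screens are exact and deterministic; ties are broken by leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "ProbeCandidate",
    "ProbeSet",
    "scan_candidates",
    "assign_modified_bases",
    "uniqueness_screen",
    "assemble_probe_set",
]

DEFAULT_OLIGO_LEN = 50
DEFAULT_GC_TARGET = 0.55
DEFAULT_GC_TOL = 0.05
DEFAULT_N_MODS = 5
DEFAULT_MIN_SPACING = 9  # "more than ~8 bases apart" -> gap of at least 9
DEFAULT_KMER = 20
DEFAULT_MAX_SPAN = 600
DEFAULT_IDEAL_SPAN = 400


@dataclass
class ProbeCandidate:
    sequence: str
    start: int  # 0-based offset on the target transcript
    gc_fraction: float
    modified_t_positions: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def end(self) -> int:
        """One past the last covered base on the transcript."""
        return self.start + len(self.sequence)


@dataclass
class ProbeSet:
    probes: list[ProbeCandidate]
    span_nt: int
    warnings: list[str] = field(default_factory=list)


def _gc(seq: str) -> float:
    return sum(1 for c in seq if c in "GCgc") / len(seq)


def scan_candidates(
    target: str,
    oligo_len: int = DEFAULT_OLIGO_LEN,
    gc_target: float = DEFAULT_GC_TARGET,
    gc_tol: float = DEFAULT_GC_TOL,
) -> list[ProbeCandidate]:
    """All windows of the target whose GC content is within tolerance.

    Windows containing ambiguous bases (anything outside ACGT) are skipped.
    """
    target = str(target).upper()
    if len(target) < oligo_len:
        raise ValueError("target shorter than the oligo length")
    out = []
    for start in range(len(target) - oligo_len + 1):
        window = target[start:start + oligo_len]
        if any(c not in "ACGT" for c in window):
            continue
        gc = _gc(window)
        if abs(gc - gc_target) <= gc_tol + 1e-12:
            out.append(ProbeCandidate(sequence=window, start=start, gc_fraction=gc))
    return out


def _max_min_spacing_subset(positions: Sequence[int], n: int) -> Optional[list[int]]:
    """Choose n positions maximizing the minimum pairwise gap.

    Among optima, returns the lexicographically smallest subset (greedy
    leftmost at the optimal gap). None when fewer than n positions exist.
    """
    pos = sorted(positions)
    if len(pos) < n:
        return None
    if n == 1:
        return [pos[0]]

    def greedy(gap: int) -> Optional[list[int]]:
        chosen = [pos[0]]
        for p in pos[1:]:
            if p - chosen[-1] >= gap:
                chosen.append(p)
                if len(chosen) == n:
                    return chosen
        return None

    lo, hi = 0, pos[-1] - pos[0]
    best = None
    while lo <= hi:  # binary search on the achievable minimum gap
        mid = (lo + hi) // 2
        sel = greedy(mid)
        if sel is not None:
            best = (mid, sel)
            lo = mid + 1
        else:
            hi = mid - 1
    if best is None:
        return None
    return greedy(best[0])


def assign_modified_bases(
    candidate: ProbeCandidate,
    n_mods: int = DEFAULT_N_MODS,
    min_spacing: int = DEFAULT_MIN_SPACING,
) -> ProbeCandidate:
    """Pick T residues to carry amino-modifications, maximally spread out.

    Selects ``n_mods`` T positions with every pairwise gap at least
    ``min_spacing`` (fluors closer than ~8 bases quench). If the oligo has
    too few T's, or no spacing-compliant selection exists, the candidate is
    flagged rather than rejected outright.
    """
    ts = [i for i, c in enumerate(candidate.sequence) if c == "T"]
    if len(ts) < n_mods:
        candidate.flags.append(f"only {len(ts)} T residues, need {n_mods}")
        candidate.modified_t_positions = ts
        return candidate
    sel = _max_min_spacing_subset(ts, n_mods)
    gaps = [b - a for a, b in zip(sel, sel[1:])]
    if gaps and min(gaps) < min_spacing:
        candidate.flags.append(
            f"modification spacing {min(gaps)} < {min_spacing}")
    candidate.modified_t_positions = sel
    return candidate


def uniqueness_screen(
    candidate: ProbeCandidate,
    background: Iterable[str],
    k: int = DEFAULT_KMER,
) -> tuple[bool, list[str]]:
    """Exact k-mer uniqueness check against background sequences.

    Fails when any length-k segment of the oligo occurs verbatim in the
    background on either strand. Returns (passed, offending k-mers).
    """
    if k > len(candidate.sequence):
        raise ValueError("k-mer longer than the oligo")
    bg_kmers: set[str] = set()
    for seq in background:
        s = str(seq).upper()
        rc = str(Seq(s).reverse_complement())
        for strand in (s, rc):
            for i in range(len(strand) - k + 1):
                bg_kmers.add(strand[i:i + k])
    offending = []
    seq = candidate.sequence.upper()
    seen = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in bg_kmers and kmer not in seen:
            offending.append(kmer)
            seen.add(kmer)
    if offending:
        candidate.flags.append(f"{len(offending)} off-target {k}-mers")
    return (not offending, offending)


def assemble_probe_set(
    candidates: Sequence[ProbeCandidate],
    set_size: int = 5,
    max_span: int = DEFAULT_MAX_SPAN,
    ideal_span: int = DEFAULT_IDEAL_SPAN,
) -> ProbeSet:
    """Choose non-overlapping candidates minimizing the transcript span.

    The span is (max end - min start) over the chosen set. Sets wider than
    ``max_span`` are infeasible (the labeled region would exceed the
    diffraction limit); spans above ``ideal_span`` carry a warning. Ties
    are broken toward the leftmost window set.
    """
    cands = sorted(candidates, key=lambda c: c.start)
    if len(cands) < set_size:
        raise ValueError(f"need at least {set_size} candidates, have {len(cands)}")
    best: Optional[list[ProbeCandidate]] = None
    best_span = None
    for i, first in enumerate(cands):
        chosen = [first]
        while len(chosen) < set_size:
            feasible = [c for c in cands[i + 1:] if c.start >= chosen[-1].end]
            if not feasible:
                break
            # earliest-ending feasible candidate minimizes the final span
            chosen.append(min(feasible, key=lambda c: (c.end, c.start)))
        if len(chosen) < set_size:
            continue
        span = chosen[-1].end - chosen[0].start
        if best_span is None or span < best_span:
            best, best_span = chosen, span
    if best is None:
        raise ValueError("no non-overlapping set of the requested size exists")
    if best_span > max_span:
        raise ValueError(
            f"best achievable span {best_span} nt exceeds the {max_span}-nt limit")
    warnings = []
    if best_span > ideal_span:
        warnings.append(f"span {best_span} nt exceeds the ideal {ideal_span} nt")
    return ProbeSet(probes=best, span_nt=best_span, warnings=warnings)
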