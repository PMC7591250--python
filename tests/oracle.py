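"""Brute-force oracles for validating the internal translated aligner.

Pure-python, full-matrix affine-gap local alignment over every (reading
frame x reference protein) pair that shares at least one exact amino-acid
k-mer with the read.  Two variants:

* ``band=None`` — exhaustive Smith-Waterman over each seeded pair.  The
  internal aligner provably matches this whenever the optimal alignment
  is gap-free or stays within the search band, which covers every read
  actually derived from a reference gene.
* ``band=<int>`` — the same DP restricted to the documented search space
  (diagonals within ``band`` of the seed-diagonal clusters), which the
  internal aligner must match on *all* inputs, including pure random
  sequence whose best chance alignments can fall outside any seed band.

Shares no code with the numba implementation: translation, seeding,
clustering and the DP are all re-derived here from the documented
contract.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_B62 = substitution_matrices.load("BLOSUM62")
_CODE = CodonTable.unambiguous_dna_by_id[1]
_STD_AA = set("ARNDCQEGHILKMFPSTWYV")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DIAG_SPAN = 64  # seeds further apart in diagonal start a new cluster
MAX_BAND_WIDTH = 2 * 15 + DIAG_SPAN + 1  # for the default band of 15


def translate_frame(seq: str, frame: int) -> str:
    """Translate one forward frame; any codon containing N gives X."""
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _CODE.stop_codons:
            out.append("*")
        else:
            out.append(_CODE.forward_table[codon])
    return "".join(out)


def six_frames(seq: str) -> list[str]:
    rc = "".join(_COMP[c] for c in reversed(seq))
    return [translate_frame(seq, f) for f in range(3)] + [
        translate_frame(rc, f) for f in range(3)
    ]


def smith_waterman(query, target, gap_open=11, gap_extend=1, dlo=None, dhi=None):
    """Full-matrix affine local alignment, optionally band-restricted.

    With ``dlo``/``dhi`` given, only cells whose diagonal ``j - i``
    (0-based) lies in ``[dlo, dhi]`` are reachable.  Returns ``(score,
    matches, columns)``: the end cell is the earliest (target pos, then
    query pos) maximum, the H state prefers diagonal over target-gap over
    query-gap on ties, and gap states prefer opening over extending.
    """
    m, n = len(query), len(target)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    ptr: dict[tuple[int, int], tuple[int, bool, bool]] = {}
    best, bi, bj = 0, -1, -1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if dlo is not None and not (dlo <= (j - 1) - (i - 1) <= dhi):
                H[i][j] = NEG
                continue
            eo = H[i][j - 1] - gap_open - gap_extend
            ee = E[i][j - 1] - gap_extend
            e, e_open = (eo, True) if eo >= ee else (ee, False)
            fo = H[i - 1][j] - gap_open - gap_extend
            fe = F[i - 1][j] - gap_extend
            f, f_open = (fo, True) if fo >= fe else (fe, False)
            hp = H[i - 1][j - 1]
            if hp == NEG and (i == 1 or j == 1):
                hp = 0  # matrix boundary always allows a fresh local start
            diag = hp + int(_B62[query[i - 1]][target[j - 1]])
            h = max(0, diag, e, f)
            if h == 0:
                src = 0
            elif diag == h:
                src = 1
            elif e == h:
                src = 2
            else:
                src = 3
            H[i][j], E[i][j], F[i][j] = h, e, f
            ptr[(i, j)] = (src, e_open, f_open)
            if h > best or (h == best and h > 0 and (j, i) < (bj, bi)):
                best, bi, bj = h, i, j
    if best <= 0:
        return 0, 0, 0
    matches = cols = 0
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        src, e_open, f_open = ptr[(i, j)]
        if state == 0:
            if src == 0:
                break
            if src == 1:
                cols += 1
                a, b = query[i - 1], target[j - 1]
                if a == b and a in _STD_AA:
                    matches += 1
                i, j = i - 1, j - 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            j -= 1
            if e_open:
                state = 0
        else:
            cols += 1
            i -= 1
            if f_open:
                state = 0
    return best, matches, cols


def _seed_clusters(frame: str, protein: str, k: int) -> list[list[int]]:
    """Greedy diagonal clusters [dlo, dhi] of exact k-mer seeds.

    Seeds are enumerated in query-position order (target positions
    ascending within one query position) and merged into the first cluster
    within ``DIAG_SPAN`` of its current range, mirroring the documented
    candidate formation.
    """
    positions: dict[str, list[int]] = {}
    for t in range(len(protein) - k + 1):
        kmer = protein[t : t + k]
        if all(c in _STD_AA for c in kmer):
            positions.setdefault(kmer, []).append(t)
    clusters: list[list[int]] = []
    for q in range(len(frame) - k + 1):
        kmer = frame[q : q + k]
        if not all(c in _STD_AA for c in kmer):
            continue
        for t in positions.get(kmer, ()):
            d = t - q
            for cl in clusters:
                if cl[0] - DIAG_SPAN <= d <= cl[1] + DIAG_SPAN:
                    cl[0] = min(cl[0], d)
                    cl[1] = max(cl[1], d)
                    break
            else:
                clusters.append([d, d])
    return clusters


def oracle_best_hit(
    read: str,
    protein_sequences: list[str],
    kmer_size: int = 5,
    gap_open: int = 11,
    gap_extend: int = 1,
    band: int | None = None,
    min_alignment_length: int = 15,
    min_report_score: int = 0,
):
    """Best hit over all seeded (frame, protein) pairs by brute-force DP.

    Returns ``(protein_index, score, matches, columns)`` or ``None`` when
    the read has no reportable hit.  Ties prefer the earliest protein in
    database order, then the earlier frame, then the earlier seed cluster.
    """
    frames = six_frames(read)
    best = None  # (score, prot_idx, frame_idx, matches, cols)
    for pi, prot in enumerate(protein_sequences):
        for fi, frame in enumerate(frames):
            clusters = _seed_clusters(frame, prot, kmer_size)
            if not clusters:
                continue
            if band is None:
                results = [smith_waterman(frame, prot, gap_open, gap_extend)]
            else:
                wmax = 2 * band + DIAG_SPAN + 1
                results = []
                for dlo, dhi in clusters:
                    lo, hi = dlo - band, dhi + band
                    if hi - lo + 1 > wmax:
                        hi = lo + wmax - 1
                    results.append(
                        smith_waterman(frame, prot, gap_open, gap_extend, lo, hi)
                    )
            for s, mt, cols in results:
                if s > 0 and (best is None or s > best[0]):
                    best = (s, pi, fi, mt, cols)
    if best is None:
        return None
    s, pi, fi, mt, cols = best
    if s < max(1, min_report_score) or cols < min_alignment_length:
        return None
    return pi, s, mt, cols
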