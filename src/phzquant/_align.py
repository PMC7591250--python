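"""Numba kernels for the internal six-frame translated protein search.

Encoding conventions shared across the package:

* nucleotides: ``A=0 C=1 G=2 T=3 N=4`` (uint8); codons are indexed in base 5
  so any codon containing ``N`` can map to ``X``;
* amino acids: index into the BLOSUM62 alphabet ``ARNDCQEGHILKMFPSTWYV BZX*``
  (codes ``>= 20`` are ambiguous/stop symbols and never participate in
  k-mer seeds or identity counts).

The search is seed-and-extend: exact amino-acid k-mers shared between a
translated frame and a catalog protein nominate (protein, diagonal-cluster)
candidates, which are scored with a banded affine-gap Smith-Waterman
centred on the seed diagonals.  With the default band the banded optimum
equals the full Smith-Waterman optimum whenever the optimal alignment stays
within ``band`` diagonals of a seed — always the case for gap-free
alignments, hence for error-free reads; the pure-python exhaustive oracle
in the test suite checks both this regime and the band-restricted contract
on arbitrary reads.

The single best alignment per read is found in two passes: a score-only
pass over every candidate, then one traceback pass on the winner to
recover identity and alignment length (reads with a single candidate go
straight to the traceback pass).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

# -- alphabets and static tables ----------------------------------------

NT_ALPHABET = "ACGTN"
NT_CODE = {c: i for i, c in enumerate(NT_ALPHABET)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
AA_CODE = {c: i for i, c in enumerate(AA_ALPHABET)}
N_AA = 20  # codes below this are unambiguous amino acids
X_CODE = AA_CODE["X"]
STOP_CODE = AA_CODE["*"]

SUBMAT = np.asarray(_BLOSUM62, dtype=np.int64)


def _build_codon_table() -> np.ndarray:
    """Base-5 codon index -> amino-acid code; any codon with N gives X."""
    table = CodonTable.unambiguous_dna_by_id[1]
    out = np.full(5 ** 3, X_CODE, dtype=np.uint8)
    for i0, b0 in enumerate("ACGT"):
        for i1, b1 in enumerate("ACGT"):
            for i2, b2 in enumerate("ACGT"):
                codon = b0 + b1 + b2
                idx = i0 * 25 + i1 * 5 + i2
                if codon in table.stop_codons:
                    out[idx] = STOP_CODE
                else:
                    out[idx] = AA_CODE[table.forward_table[codon]]
    return out


CODON_TABLE = _build_codon_table()


def _build_rc_codon_table() -> np.ndarray:
    """Base-5 index of a codon -> amino acid of its reverse complement."""
    out = np.empty_like(CODON_TABLE)
    for i0 in range(5):
        for i1 in range(5):
            for i2 in range(5):
                r0 = 3 - i2 if i2 < 4 else 4
                r1 = 3 - i1 if i1 < 4 else 4
                r2 = 3 - i0 if i0 < 4 else 4
                out[i0 * 25 + i1 * 5 + i2] = CODON_TABLE[r0 * 25 + r1 * 5 + r2]
    return out


RC_CODON_TABLE = _build_rc_codon_table()

_NEG = np.int64(-(10 ** 9))
_MAX_CAND = 1024  # per-read candidate (protein, diagonal-cluster) capacity
_DIAG_SPAN = 64   # seed diagonals further apart start a new candidate


# -- encoding helpers ----------------------------------------------------

def _make_lookup(alphabet: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return lut


_NT_LOOKUP = _make_lookup(NT_ALPHABET)
_AA_LOOKUP = _make_lookup(AA_ALPHABET)


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; reject unknown characters."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = _NT_LOOKUP[arr]
    if (out == 255).any():
        bad = sorted({chr(b) for b in arr[out == 255]})
        raise ValueError(f"invalid nucleotide characters: {bad}")
    return out


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein string to BLOSUM62 alphabet codes (unknown -> X)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = _AA_LOOKUP[arr]
    out[out == 255] = X_CODE
    return out


# -- catalog packing -----------------------------------------------------

class PackedCatalog:
    """Flat-array view of a catalog for the numba kernels.

    Holds the concatenated amino-acid codes, per-protein offsets, a
    bit-packed k-mer presence filter and a CSR index mapping k-mer hash ->
    (protein, position) seed entries.  Protein index equals catalog
    (database) order, so index comparisons implement first-occurrence
    tie-breaking.
    """

    def __init__(self, sequences: list[str], kmer_size: int = 5):
        if not 3 <= kmer_size <= 5:
            raise ValueError("kmer_size must be between 3 and 5")
        self.kmer_size = kmer_size
        codes = [encode_aa(s) for s in sequences]
        self.offsets = np.zeros(len(codes) + 1, dtype=np.int64)
        self.offsets[1:] = np.cumsum([len(c) for c in codes])
        self.seq = np.concatenate(codes).astype(np.uint8) if codes else np.zeros(0, np.uint8)

        k = kmer_size
        hashes, prots, positions = [], [], []
        for pi, c in enumerate(codes):
            if len(c) < k:
                continue
            valid = c < N_AA
            h = np.zeros(len(c) - k + 1, dtype=np.int64)
            ok = np.ones(len(c) - k + 1, dtype=bool)
            for j in range(k):
                h = h * N_AA + c[j : len(c) - k + 1 + j]
                ok &= valid[j : len(c) - k + 1 + j]
            hashes.append(h[ok])
            prots.append(np.full(int(ok.sum()), pi, dtype=np.int32))
            positions.append(np.nonzero(ok)[0].astype(np.int32))
        if hashes:
            h = np.concatenate(hashes)
            p = np.concatenate(prots)
            q = np.concatenate(positions)
        else:
            h = np.zeros(0, np.int64)
            p = q = np.zeros(0, np.int32)
        order = np.argsort(h, kind="stable")
        h, self.kmer_prot, self.kmer_pos = h[order], p[order], q[order]
        n_kmers = N_AA ** k
        self.kmer_start = np.searchsorted(h, np.arange(n_kmers + 1)).astype(np.int32)
        # bit-packed presence filter: bit (h & 7) of byte (h >> 3)
        self.kmer_bits = np.zeros((n_kmers + 7) // 8, dtype=np.uint8)
        uh = np.unique(h)
        np.bitwise_or.at(self.kmer_bits, uh >> 3, (1 << (uh & 7)).astype(np.uint8))


# -- kernels -------------------------------------------------------------

@njit(cache=False)
def _translate_frames(read, rlen, codon_tab, rc_codon_tab, pep, plens):
    """Fill pep[(6, maxpep)] with the 6 frame translations of one read.

    One rolling base-5 scan of the read serves both strands: the reverse
    complement of the codon starting at p is the codon at reverse-strand
    position ``rlen - 3 - p``.
    """
    for f in range(3):
        n = (rlen - f) // 3
        plens[f] = n
        plens[3 + f] = n
    if rlen < 3:
        return
    idx = np.int64(read[0]) * 5 + read[1]
    for p in range(rlen - 2):
        idx = (idx % 25) * 5 + read[p + 2]
        pep[p % 3, p // 3] = codon_tab[idx]
        q = rlen - 3 - p
        pep[3 + q % 3, q // 3] = rc_codon_tab[idx]


@njit(cache=False, inline="always")
def _build_profile(q, qlen, sub, prof):
    """Query profile: prof[aa, i] = sub[q[i], aa] (Farrar-style)."""
    for i in range(qlen):
        subrow = sub[q[i]]
        for aa in range(prof.shape[0]):
            prof[aa, i] = subrow[aa]


@njit(cache=False, inline="always")
def _banded_sw_score(prof, qlen, cat, t0, tlen, dlo, dhi, go, ge, Hp, Hc, Ep, Ec):
    """Score-only banded affine local alignment (column-major).

    Band: target position j satisfies i + dlo <= j <= i + dhi.  Columns
    iterate over j; the row coordinate within a column is r = i - (j -
    dhi), stored at padded index r + 1.  The target-gap state E crosses
    columns and is stored; the query-gap state F is intra-column and
    handled by a sequential fix-up pass.  Returns the best local score.
    """
    w = dhi - dlo + 1
    jlo = dlo if dlo > 0 else 0
    jhi = qlen - 1 + dhi
    if jhi > tlen - 1:
        jhi = tlen - 1
    init = 0 if jlo == 0 else _NEG  # column -1 is the matrix boundary only if j=0
    for r in range(w + 3):
        Hp[r] = init
        Ep[r] = _NEG
    best = np.int64(0)
    goe = go + ge
    for j in range(jlo, jhi + 1):
        jd = j - dhi
        rlo = 0 if jd >= 0 else -jd
        rhi = w - 1
        if qlen - 1 - jd < rhi:
            rhi = qlen - 1 - jd
        if rhi < rlo:
            Hc[rlo] = _NEG
            Hp, Hc = Hc, Hp
            Ep, Ec = Ec, Ep
            continue
        Pa = prof[cat[t0 + j]]
        # pass 1: diagonal and target-gap states (no intra-column deps)
        for r in range(rlo, rhi + 1):
            diag = Hp[r + 1] + Pa[r + jd]
            e = max(Hp[r + 2] - goe, Ep[r + 2] - ge)
            Hc[r + 1] = max(0, max(diag, e))
            Ec[r + 1] = e
        if jd <= 0:
            # cell at i == 0: the top boundary allows a fresh start
            Hc[-jd + 1] = max(Hc[-jd + 1], np.int64(Pa[0]))
        # pass 2: query-gap (F) fix-up, sequential down the column
        f = _NEG
        hup = 0 if jd <= 0 else _NEG  # H(i-1, j) above the first row
        for r in range(rlo, rhi + 1):
            f = max(hup - goe, f - ge)
            h = Hc[r + 1]
            if f > h:
                h = f
                Hc[r + 1] = h
            best = max(best, h)
            hup = h
        # pad sentinels so the next (shifted) column reads _NEG off-band
        Hc[rlo] = _NEG
        Hc[rhi + 2] = _NEG
        Ec[rhi + 2] = _NEG
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep
    return best


@njit(cache=False)
def _banded_sw_trace(prof, q, qlen, cat, t0, tlen, dlo, dhi, go, ge,
                     Hp, Hc, Ep, Ec, ptr):
    """Banded affine local alignment with traceback (column-major).

    Pointer codes per cell (bits): 0-1 H source (0 stop, 1 diag, 2 E, 3 F),
    bit 2: E opened from H, bit 3: F opened from H.  Ties prefer the
    earliest end cell in column-major order (target, then query position),
    diagonal over E over F, and opening over extending.  Returns
    (score, matches, columns).
    """
    w = dhi - dlo + 1
    jlo = dlo if dlo > 0 else 0
    jhi = qlen - 1 + dhi
    if jhi > tlen - 1:
        jhi = tlen - 1
    init = 0 if jlo == 0 else _NEG
    for r in range(w + 3):
        Hp[r] = init
        Ep[r] = _NEG
    best = np.int64(0)
    bi = -1
    bj = -1
    goe = go + ge
    for j in range(jlo, jhi + 1):
        jd = j - dhi
        prow = ptr[j - jlo]
        rlo = 0 if jd >= 0 else -jd
        rhi = w - 1
        if qlen - 1 - jd < rhi:
            rhi = qlen - 1 - jd
        if rhi < rlo:
            Hc[rlo] = _NEG
            Hp, Hc = Hc, Hp
            Ep, Ec = Ec, Ep
            continue
        Pa = prof[cat[t0 + j]]
        for r in range(rlo, rhi + 1):
            diag = Hp[r + 1] + Pa[r + jd]
            eo = Hp[r + 2] - goe
            ee = Ep[r + 2] - ge
            e = max(eo, ee)
            bits = np.uint8(4) if eo >= ee else np.uint8(0)
            h = max(0, max(diag, e))
            if h > 0:
                if diag == h:
                    bits |= np.uint8(1)
                else:
                    bits |= np.uint8(2)
            Hc[r + 1] = h
            Ec[r + 1] = e
            prow[r] = bits
        if jd <= 0:
            r0 = -jd
            d0 = np.int64(Pa[0])
            if d0 >= Hc[r0 + 1] and d0 > 0:
                Hc[r0 + 1] = d0
                prow[r0] = (prow[r0] & np.uint8(12)) | np.uint8(1)
        f = _NEG
        hup = 0 if jd <= 0 else _NEG
        for r in range(rlo, rhi + 1):
            fo = hup - goe
            fe = f - ge
            f = max(fo, fe)
            if fo >= fe:
                prow[r] |= np.uint8(8)
            h = Hc[r + 1]
            if f > h:
                h = f
                Hc[r + 1] = h
                prow[r] = (prow[r] & np.uint8(12)) | np.uint8(3)
            if h > best:
                best = h
                bi = r + jd
                bj = j
            hup = h
        Hc[rlo] = _NEG
        Hc[rhi + 2] = _NEG
        Ec[rhi + 2] = _NEG
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep

    matches = 0
    cols = 0
    if best <= 0:
        return best, matches, cols
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i >= 0 and j >= jlo:
        p = ptr[j - jlo, i - (j - dhi)]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                cols += 1
                if q[i] < N_AA and q[i] == cat[t0 + j]:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E: gap in query, consumes target
            cols += 1
            j -= 1
            if (p & 4) != 0:
                state = 0
        else:  # F: gap in target, consumes query
            cols += 1
            i -= 1
            if (p & 8) != 0:
                state = 0
    return best, matches, cols


@njit(cache=False)
def _search_chunk(reads, rlens, codon_tab, rc_codon_tab, sub,
                  k, kmer_bits, kmer_start, kmer_prot, kmer_pos,
                  cat, cat_off,
                  band, go, ge, min_cols, min_report,
                  out_prot, out_score, out_match, out_cols, out_frame):
    n = reads.shape[0]
    maxpep = reads.shape[1] // 3 + 1
    pep = np.zeros((6, maxpep), dtype=np.uint8)
    plens = np.zeros(6, dtype=np.int64)
    prof = np.zeros((sub.shape[0], maxpep), dtype=np.int64)
    wmax = 2 * band + _DIAG_SPAN + 1
    Hp = np.zeros(wmax + 3, dtype=np.int64)
    Hc = np.zeros(wmax + 3, dtype=np.int64)
    Ep = np.zeros(wmax + 3, dtype=np.int64)
    Ec = np.zeros(wmax + 3, dtype=np.int64)
    ptr = np.zeros((maxpep + wmax, wmax), dtype=np.uint8)
    cand_prot = np.zeros(_MAX_CAND, dtype=np.int64)
    cand_frame = np.zeros(_MAX_CAND, dtype=np.int64)
    cand_dlo = np.zeros(_MAX_CAND, dtype=np.int64)
    cand_dhi = np.zeros(_MAX_CAND, dtype=np.int64)
    floor = min_report if min_report > 1 else 1

    for r in range(n):
        rlen = rlens[r]
        out_prot[r] = -1
        if rlen < 3 * k:
            continue
        _translate_frames(reads[r], rlen, codon_tab, rc_codon_tab, pep, plens)

        ncand = 0
        for f in range(6):
            plen = plens[f]
            run = 0  # current run of unambiguous residues
            h = np.int64(0)
            hmod = np.int64(N_AA ** (k - 1))
            for p0 in range(plen):
                c = pep[f, p0]
                if c >= N_AA:
                    run = 0
                    h = 0
                    continue
                # rolling base-20 hash over the trailing k residues
                h = (h % hmod) * N_AA + c
                run += 1
                if run < k:
                    continue
                if (kmer_bits[h >> 3] >> (h & 7)) & 1 == 0:
                    continue
                q0 = p0 - k + 1
                for e in range(kmer_start[h], kmer_start[h + 1]):
                    prot = kmer_prot[e]
                    d = kmer_pos[e] - q0
                    found = False
                    for ci in range(ncand):
                        if cand_prot[ci] == prot and cand_frame[ci] == f:
                            if cand_dlo[ci] - _DIAG_SPAN <= d <= cand_dhi[ci] + _DIAG_SPAN:
                                if d < cand_dlo[ci]:
                                    cand_dlo[ci] = d
                                if d > cand_dhi[ci]:
                                    cand_dhi[ci] = d
                                found = True
                                break
                    if not found and ncand < _MAX_CAND:
                        cand_prot[ncand] = prot
                        cand_frame[ncand] = f
                        cand_dlo[ncand] = d
                        cand_dhi[ncand] = d
                        ncand += 1
        if ncand == 0:
            continue

        prof_frame = -1
        if ncand == 1:
            best_ci = 0
        else:
            best_score = np.int64(0)
            best_ci = -1
            for ci in range(ncand):
                f = cand_frame[ci]
                prot = cand_prot[ci]
                t0 = cat_off[prot]
                tlen = cat_off[prot + 1] - t0
                dlo = cand_dlo[ci] - band
                dhi = cand_dhi[ci] + band
                if dhi - dlo + 1 > wmax:
                    dhi = dlo + wmax - 1
                if f != prof_frame:
                    _build_profile(pep[f], plens[f], sub, prof)
                    prof_frame = f
                s = _banded_sw_score(
                    prof, plens[f], cat, t0, tlen, dlo, dhi, go, ge,
                    Hp, Hc, Ep, Ec,
                )
                if s > best_score:
                    best_score = s
                    best_ci = ci
                elif s == best_score and best_ci >= 0:
                    # tie: first occurrence in the database wins, then frame
                    if prot < cand_prot[best_ci] or (
                        prot == cand_prot[best_ci] and f < cand_frame[best_ci]
                    ):
                        best_ci = ci
            if best_ci < 0 or best_score < floor:
                continue

        f = cand_frame[best_ci]
        prot = cand_prot[best_ci]
        t0 = cat_off[prot]
        tlen = cat_off[prot + 1] - t0
        dlo = cand_dlo[best_ci] - band
        dhi = cand_dhi[best_ci] + band
        if dhi - dlo + 1 > wmax:
            dhi = dlo + wmax - 1
        if f != prof_frame:
            _build_profile(pep[f], plens[f], sub, prof)
            prof_frame = f
        s, matches, cols = _banded_sw_trace(
            prof, pep[f], plens[f], cat, t0, tlen, dlo, dhi, go, ge,
            Hp, Hc, Ep, Ec, ptr,
        )
        if s < floor or cols < min_cols:
            continue
        out_prot[r] = prot
        out_score[r] = s
        out_match[r] = matches
        out_cols[r] = cols
        out_frame[r] = f
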