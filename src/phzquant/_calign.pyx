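# cython: boundscheck=False, wraparound=False, cdivision=True, initializedcheck=False
"""Compiled hot path of the translated best-hit search.

Seeding and candidate formation are Cython; the banded affine
Smith-Waterman cores (SSE2-vectorized score pass, scalar traceback) live
in ``_swsimd.h``.  Semantics mirror the numba kernels in
``phzquant._align`` exactly; the pure-python oracle tests and a numba/C
equivalence test pin the implementations together.
"""

from libc.stdlib cimport malloc, free
from libc.stdint cimport int16_t, int64_t, uint8_t

cdef extern from "_swsimd.h":
    void phz_build_profile(const uint8_t *q, long qlen, const int64_t *sub,
                           int n_alpha, int16_t *prof, int maxpep) nogil
    int phz_banded_score(const int16_t *prof, int maxpep, long qlen,
                         const uint8_t *cat, long t0, long tlen,
                         long dlo, long dhi, int go, int ge,
                         int16_t *Hp, int16_t *Hc, int16_t *Ep, int16_t *Ec) nogil
    int phz_banded_trace(const int16_t *prof, int maxpep,
                         const uint8_t *q, long qlen,
                         const uint8_t *cat, long t0, long tlen,
                         long dlo, long dhi, int go, int ge,
                         int16_t *Hp, int16_t *Hc, int16_t *Ep, int16_t *Ec,
                         uint8_t *ptr, int wmax,
                         int *out_matches, int *out_cols) nogil

cdef int N_AA = 20
cdef int DIAG_SPAN = 64
cdef int MAX_CAND = 1024


cdef void _translate(const unsigned char *read, int rlen,
                     const unsigned char *codon_tab, const unsigned char *rc_codon_tab,
                     unsigned char *pep, int maxpep, long *plens) nogil:
    cdef int f, p, q, idx
    for f in range(3):
        plens[f] = (rlen - f) // 3
        plens[3 + f] = (rlen - f) // 3
    if rlen < 3:
        return
    idx = read[0] * 5 + read[1]
    for p in range(rlen - 2):
        idx = (idx % 25) * 5 + read[p + 2]
        pep[(p % 3) * maxpep + p // 3] = codon_tab[idx]
        q = rlen - 3 - p
        pep[(3 + q % 3) * maxpep + q // 3] = rc_codon_tab[idx]


def search_chunk(const unsigned char[:, ::1] reads, const long long[::1] rlens,
                 const unsigned char[::1] codon_tab, const unsigned char[::1] rc_codon_tab,
                 const int64_t[:, ::1] sub,
                 int k, const unsigned char[::1] kmer_bits, const int[::1] kmer_start,
                 const int[::1] kmer_prot, const int[::1] kmer_pos,
                 const unsigned char[::1] cat, const long long[::1] cat_off,
                 int band, int go, int ge, int min_cols, int min_report,
                 int[::1] out_prot, int[::1] out_score,
                 int[::1] out_match, int[::1] out_cols, signed char[::1] out_frame):
    """Per-read best-hit search over an encoded read matrix (C hot path)."""
    cdef Py_ssize_t n = reads.shape[0]
    cdef int maxpep = <int> (reads.shape[1] // 3 + 1)
    cdef int n_alpha = <int> sub.shape[0]
    cdef int wmax = 2 * band + DIAG_SPAN + 1
    cdef int floor = min_report if min_report > 1 else 1

    cdef unsigned char *pep = <unsigned char *> malloc(6 * maxpep)
    cdef long plens[6]
    cdef int16_t *prof = <int16_t *> malloc(n_alpha * maxpep * sizeof(int16_t))
    cdef int16_t *Hp = <int16_t *> malloc((wmax + 11) * sizeof(int16_t))
    cdef int16_t *Hc = <int16_t *> malloc((wmax + 11) * sizeof(int16_t))
    cdef int16_t *Ep = <int16_t *> malloc((wmax + 11) * sizeof(int16_t))
    cdef int16_t *Ec = <int16_t *> malloc((wmax + 11) * sizeof(int16_t))
    cdef unsigned char *ptr = <unsigned char *> malloc((maxpep + wmax) * wmax)
    cdef long *cand_prot = <long *> malloc(MAX_CAND * sizeof(long))
    cdef long *cand_frame = <long *> malloc(MAX_CAND * sizeof(long))
    cdef long *cand_dlo = <long *> malloc(MAX_CAND * sizeof(long))
    cdef long *cand_dhi = <long *> malloc(MAX_CAND * sizeof(long))
    if (pep == NULL or prof == NULL or Hp == NULL or Hc == NULL or Ep == NULL
            or Ec == NULL or ptr == NULL or cand_prot == NULL or cand_frame == NULL
            or cand_dlo == NULL or cand_dhi == NULL):
        raise MemoryError

    cdef Py_ssize_t r_i
    cdef long rlen, h, hmod, q0, d, plen
    cdef int f, ncand, ci, run, c, best_ci, s, matches, cols, e
    cdef int best_score, prof_frame
    cdef long prot, t0, tlen, dlo, dhi
    cdef int found
    cdef const unsigned char *pepf

    hmod = 1
    for c in range(k - 1):
        hmod *= N_AA

    with nogil:
        for r_i in range(n):
            rlen = <long> rlens[r_i]
            out_prot[r_i] = -1
            if rlen < 3 * k:
                continue
            _translate(&reads[r_i, 0], <int> rlen, &codon_tab[0], &rc_codon_tab[0],
                       pep, maxpep, plens)

            ncand = 0
            for f in range(6):
                plen = plens[f]
                pepf = pep + f * maxpep
                run = 0
                h = 0
                for c in range(<int> plen):
                    if pepf[c] >= N_AA:
                        run = 0
                        h = 0
                        continue
                    h = (h % hmod) * N_AA + pepf[c]
                    run += 1
                    if run < k:
                        continue
                    if not ((kmer_bits[h >> 3] >> (h & 7)) & 1):
                        continue
                    q0 = c - k + 1
                    for e in range(kmer_start[h], kmer_start[h + 1]):
                        prot = kmer_prot[e]
                        d = kmer_pos[e] - q0
                        found = 0
                        for ci in range(ncand):
                            if cand_prot[ci] == prot and cand_frame[ci] == f:
                                if cand_dlo[ci] - DIAG_SPAN <= d <= cand_dhi[ci] + DIAG_SPAN:
                                    if d < cand_dlo[ci]:
                                        cand_dlo[ci] = d
                                    if d > cand_dhi[ci]:
                                        cand_dhi[ci] = d
                                    found = 1
                                    break
                        if not found and ncand < MAX_CAND:
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
                best_score = 0
                best_ci = -1
                for ci in range(ncand):
                    f = <int> cand_frame[ci]
                    prot = cand_prot[ci]
                    t0 = cat_off[prot]
                    tlen = cat_off[prot + 1] - t0
                    dlo = cand_dlo[ci] - band
                    dhi = cand_dhi[ci] + band
                    if dhi - dlo + 1 > wmax:
                        dhi = dlo + wmax - 1
                    if f != prof_frame:
                        phz_build_profile(pep + f * maxpep, plens[f], &sub[0, 0],
                                          n_alpha, prof, maxpep)
                        prof_frame = f
                    s = phz_banded_score(prof, maxpep, plens[f], &cat[0], t0, tlen,
                                         dlo, dhi, go, ge, Hp, Hc, Ep, Ec)
                    if s > best_score:
                        best_score = s
                        best_ci = ci
                    elif s == best_score and best_ci >= 0:
                        if cand_prot[ci] < cand_prot[best_ci] or (
                            cand_prot[ci] == cand_prot[best_ci]
                            and cand_frame[ci] < cand_frame[best_ci]
                        ):
                            best_ci = ci
                if best_ci < 0 or best_score < floor:
                    continue

            f = <int> cand_frame[best_ci]
            prot = cand_prot[best_ci]
            t0 = cat_off[prot]
            tlen = cat_off[prot + 1] - t0
            dlo = cand_dlo[best_ci] - band
            dhi = cand_dhi[best_ci] + band
            if dhi - dlo + 1 > wmax:
                dhi = dlo + wmax - 1
            if f != prof_frame:
                phz_build_profile(pep + f * maxpep, plens[f], &sub[0, 0],
                                  n_alpha, prof, maxpep)
                prof_frame = f
            s = phz_banded_trace(prof, maxpep, pep + f * maxpep, plens[f], &cat[0],
                                 t0, tlen, dlo, dhi, go, ge, Hp, Hc, Ep, Ec,
                                 ptr, wmax, &matches, &cols)
            if s < floor or cols < min_cols:
                continue
            out_prot[r_i] = <int> prot
            out_score[r_i] = s
            out_match[r_i] = matches
            out_cols[r_i] = cols
            out_frame[r_i] = <signed char> f

    free(pep); free(prof); free(Hp); free(Hc); free(Ep); free(Ec); free(ptr)
    free(cand_prot); free(cand_frame); free(cand_dlo); free(cand_dhi)
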