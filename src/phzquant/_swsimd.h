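/* Banded affine local alignment cores for the translated search.
 *
 * Column-major banded Smith-Waterman with a Farrar-style query profile.
 * The score-only pass is vectorized with SSE2 int16 intrinsics (8 lanes)
 * where available, with a scalar fallback; the traceback variant is
 * scalar.  Semantics (band geometry, tie preferences, boundary fresh
 * starts) match the numba reference kernels exactly.
 */
#ifndef PHZ_SWSIMD_H
#define PHZ_SWSIMD_H

#include <stdint.h>

#if defined(__SSE2__) || defined(_M_X64) || defined(__x86_64__)
#define PHZ_HAVE_SSE2 1
#include <emmintrin.h>
#endif

#define PHZ_NEG (-4096)

static inline int phz_imax(int a, int b) { return a > b ? a : b; }

static void phz_build_profile(const uint8_t *q, long qlen, const int64_t *sub,
                              int n_alpha, int16_t *prof, int maxpep)
{
    long i;
    int aa;
    for (i = 0; i < qlen; i++) {
        const int64_t *subrow = sub + (long)q[i] * n_alpha;
        for (aa = 0; aa < n_alpha; aa++)
            prof[(long)aa * maxpep + i] = (int16_t)subrow[aa];
    }
}

/* Score-only banded local alignment; returns the best local score. */
static int phz_banded_score(const int16_t *prof, int maxpep, long qlen,
                            const uint8_t *cat, long t0, long tlen,
                            long dlo, long dhi, int go, int ge,
                            int16_t *Hp, int16_t *Hc, int16_t *Ep, int16_t *Ec)
{
    long w = dhi - dlo + 1;
    long jlo = dlo > 0 ? dlo : 0;
    long jhi = qlen - 1 + dhi;
    long j, jd, rlo, rhi, r;
    int best = 0, goe = go + ge;
    int16_t init;
    int16_t *tmp;
    if (jhi > tlen - 1)
        jhi = tlen - 1;
    init = (jlo == 0) ? 0 : PHZ_NEG;
    for (r = 0; r < w + 3; r++) {
        Hp[r] = init;
        Ep[r] = PHZ_NEG;
    }
#ifdef PHZ_HAVE_SSE2
    __m128i vgoe = _mm_set1_epi16((int16_t)goe);
    __m128i vge = _mm_set1_epi16((int16_t)ge);
    __m128i vzero = _mm_setzero_si128();
#endif
    for (j = jlo; j <= jhi; j++) {
        const int16_t *Pa0;
        int16_t f, hup, h;
        jd = j - dhi;
        rlo = jd >= 0 ? 0 : -jd;
        rhi = w - 1;
        if (qlen - 1 - jd < rhi)
            rhi = qlen - 1 - jd;
        if (rhi < rlo) {
            Hc[rlo] = PHZ_NEG;
            tmp = Hp; Hp = Hc; Hc = tmp;
            tmp = Ep; Ep = Ec; Ec = tmp;
            continue;
        }
        Pa0 = prof + (long)cat[t0 + j] * maxpep;
        r = rlo;
#ifdef PHZ_HAVE_SSE2
        for (; r + 8 <= rhi + 1; r += 8) {
            __m128i hp1 = _mm_loadu_si128((const __m128i *)(Hp + r + 1));
            __m128i hp2 = _mm_loadu_si128((const __m128i *)(Hp + r + 2));
            __m128i ep2 = _mm_loadu_si128((const __m128i *)(Ep + r + 2));
            __m128i pa = _mm_loadu_si128((const __m128i *)(Pa0 + r + jd));
            __m128i diag = _mm_adds_epi16(hp1, pa);
            __m128i e = _mm_max_epi16(_mm_subs_epi16(hp2, vgoe),
                                      _mm_subs_epi16(ep2, vge));
            __m128i hv = _mm_max_epi16(vzero, _mm_max_epi16(diag, e));
            _mm_storeu_si128((__m128i *)(Hc + r + 1), hv);
            _mm_storeu_si128((__m128i *)(Ec + r + 1), e);
        }
#endif
        for (; r <= rhi; r++) {
            int diag = Hp[r + 1] + Pa0[r + jd];
            int e = phz_imax(Hp[r + 2] - goe, Ep[r + 2] - ge);
            int hh = phz_imax(0, phz_imax(diag, e));
            Hc[r + 1] = (int16_t)hh;
            Ec[r + 1] = (int16_t)(e < PHZ_NEG ? PHZ_NEG : e);
        }
        if (jd <= 0) {
            int16_t d0 = Pa0[0];
            if (d0 > Hc[-jd + 1])
                Hc[-jd + 1] = d0;
        }
        /* query-gap (F) fix-up, sequential down the column */
        f = PHZ_NEG;
        hup = (jd <= 0) ? 0 : PHZ_NEG;
        for (r = rlo; r <= rhi; r++) {
            int fo = hup - goe;
            int fe = f - ge;
            int ff = phz_imax(fo, fe);
            f = (int16_t)(ff < PHZ_NEG ? PHZ_NEG : ff);
            h = Hc[r + 1];
            if (f > h) {
                h = f;
                Hc[r + 1] = h;
            }
            if (h > best)
                best = h;
            hup = h;
        }
        Hc[rlo] = PHZ_NEG;
        Hc[rhi + 2] = PHZ_NEG;
        Ec[rhi + 2] = PHZ_NEG;
        tmp = Hp; Hp = Hc; Hc = tmp;
        tmp = Ep; Ep = Ec; Ec = tmp;
    }
    return best;
}

/* Banded local alignment with traceback; fills matches/columns of the
 * single best alignment (earliest end cell in column-major order). */
static int phz_banded_trace(const int16_t *prof, int maxpep,
                            const uint8_t *q, long qlen,
                            const uint8_t *cat, long t0, long tlen,
                            long dlo, long dhi, int go, int ge,
                            int16_t *Hp, int16_t *Hc, int16_t *Ep, int16_t *Ec,
                            uint8_t *ptr, int wmax,
                            int *out_matches, int *out_cols)
{
    long w = dhi - dlo + 1;
    long jlo = dlo > 0 ? dlo : 0;
    long jhi = qlen - 1 + dhi;
    long j, jd, rlo, rhi, r, bi = -1, bj = -1, i;
    int best = 0, goe = go + ge;
    int16_t init;
    int16_t *tmp;
    int state, matches = 0, cols = 0;
    if (jhi > tlen - 1)
        jhi = tlen - 1;
    init = (jlo == 0) ? 0 : PHZ_NEG;
    for (r = 0; r < w + 3; r++) {
        Hp[r] = init;
        Ep[r] = PHZ_NEG;
    }
    for (j = jlo; j <= jhi; j++) {
        const int16_t *Pa0;
        uint8_t *prow;
        int f, hup;
        jd = j - dhi;
        prow = ptr + (j - jlo) * wmax;
        rlo = jd >= 0 ? 0 : -jd;
        rhi = w - 1;
        if (qlen - 1 - jd < rhi)
            rhi = qlen - 1 - jd;
        if (rhi < rlo) {
            Hc[rlo] = PHZ_NEG;
            tmp = Hp; Hp = Hc; Hc = tmp;
            tmp = Ep; Ep = Ec; Ec = tmp;
            continue;
        }
        Pa0 = prof + (long)cat[t0 + j] * maxpep;
        for (r = rlo; r <= rhi; r++) {
            int diag = Hp[r + 1] + Pa0[r + jd];
            int eo = Hp[r + 2] - goe;
            int ee = Ep[r + 2] - ge;
            int e = phz_imax(eo, ee);
            uint8_t bits = (eo >= ee) ? 4 : 0;
            int h = phz_imax(0, phz_imax(diag, e));
            if (h > 0)
                bits |= (diag == h) ? 1 : 2;
            Hc[r + 1] = (int16_t)h;
            Ec[r + 1] = (int16_t)(e < PHZ_NEG ? PHZ_NEG : e);
            prow[r] = bits;
        }
        if (jd <= 0) {
            long r0 = -jd;
            int d0 = Pa0[0];
            if (d0 >= Hc[r0 + 1] && d0 > 0) {
                Hc[r0 + 1] = (int16_t)d0;
                prow[r0] = (uint8_t)((prow[r0] & 12) | 1);
            }
        }
        f = PHZ_NEG;
        hup = (jd <= 0) ? 0 : PHZ_NEG;
        for (r = rlo; r <= rhi; r++) {
            int fo = hup - goe;
            int fe = f - ge;
            int h;
            f = phz_imax(fo, fe);
            if (f < PHZ_NEG)
                f = PHZ_NEG;
            if (fo >= fe)
                prow[r] |= 8;
            h = Hc[r + 1];
            if (f > h) {
                h = f;
                Hc[r + 1] = (int16_t)h;
                prow[r] = (uint8_t)((prow[r] & 12) | 3);
            }
            if (h > best) {
                best = h;
                bi = r + jd;
                bj = j;
            }
            hup = h;
        }
        Hc[rlo] = PHZ_NEG;
        Hc[rhi + 2] = PHZ_NEG;
        Ec[rhi + 2] = PHZ_NEG;
        tmp = Hp; Hp = Hc; Hc = tmp;
        tmp = Ep; Ep = Ec; Ec = tmp;
    }

    if (best <= 0) {
        *out_matches = 0;
        *out_cols = 0;
        return best;
    }
    i = bi;
    j = bj;
    state = 0;
    while (i >= 0 && j >= jlo) {
        uint8_t p = ptr[(j - jlo) * wmax + (i - (j - dhi))];
        if (state == 0) {
            int src = p & 3;
            if (src == 0)
                break;
            if (src == 1) {
                cols++;
                if (q[i] < 20 && q[i] == cat[t0 + j])
                    matches++;
                i--;
                j--;
            } else if (src == 2) {
                state = 1;
            } else {
                state = 2;
            }
        } else if (state == 1) { /* E: gap in query, consumes target */
            cols++;
            j--;
            if (p & 4)
                state = 0;
        } else { /* F: gap in target, consumes query */
            cols++;
            i--;
            if (p & 8)
                state = 0;
        }
    }
    *out_matches = matches;
    *out_cols = cols;
    return best;
}

#endif /* PHZ_SWSIMD_H */
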