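"""Numba kernels for the semi-Markov Viterbi sweep.

One left-to-right pass over a contig processes candidate signal positions
(ATG / GT / AG / stop on the forward strand, their reverse-complement
mirrors on the reverse strand) as events.  Each event closes variable-length
segments by a windowed max over compatible predecessor events; segment
emissions come from phased prefix-sum arrays so every lookback is O(1)
per predecessor.

Conventions mirrored exactly by ``score_parse``:
  * coordinates 0-based half-open; ``cf[g]``/``cr[g]`` are phased coding
    prefix sums (forward / reverse shadow states), ``cnf``/``cnr``
    non-coding prefix sums;
  * genic durations are hard-capped at their L_max (no tail in decoding);
    the intergenic state has a histogram body plus a geometric tail handled
    by a running max;
  * genic segments may not overlap a masked run longer than the configured
    gap (``bar_lo`` clip); intergenic may;
  * in-frame stop codons are excluded via per-frame-class "last aligned
    stop" clips, and stops split by an intron via donor/acceptor flank
    codes checked when an intron closes.

Ties resolve to the higher score, then fewer segments, then the earliest-
scanned predecessor (candidates are scanned in increasing position order).
"""

import numpy as np
from numba import njit

NEG = -1.0e18

# fpar layout
LP_SINGLE, LP_MULTI, LP_CONT, LP_TERM, LP_FWD, LP_REV, \
    IG_TAIL_LOGMASS, IG_LOG_R, IG_LOG_1MR, REWARD = range(10)
# ipar layout
N_, MIN_I, MAX_I, MIN_EI, MAX_EI, MIN_EN, MAX_EN, MIN_ET, MAX_ET, \
    MIN_S, MAX_S, MIN_IG, MAX_IG = range(13)


@njit(cache=True, inline="always")
def _is_stop(a, b, c):
    # TAA, TAG, TGA with A=0 C=1 G=2 T=3
    return (a == 3 and b == 0 and c == 0) or \
           (a == 3 and b == 0 and c == 2) or \
           (a == 3 and b == 2 and c == 0)


@njit(cache=True, inline="always")
def _is_rstop(a, b, c):
    # TTA, CTA, TCA (reverse-complement images of the stops)
    return (a == 3 and b == 3 and c == 0) or \
           (a == 1 and b == 3 and c == 0) or \
           (a == 3 and b == 1 and c == 0)


@njit(cache=True)
def _find_con(con_end, con_start, e, d):
    """True iff a constrained junction with exactly this (start, end)."""
    lo = np.searchsorted(con_end, e)
    while lo < con_end.shape[0] and con_end[lo] == e:
        if con_start[lo] == d:
            return True
        lo += 1
    return False


@njit(cache=True)
def sweep(ipar, fpar, codes,
          cf, cr, cnf, cnr, bar_lo, last_stop_f, last_stop_r,
          dur_i, dur_ei, dur_en, dur_et, dur_s, dur_ig, ig_sf,
          Sf, Df, Af, Tf, Lr, Dr, Ar, Rr,
          sS, sD, sA, sT, sL, sDr, sAr, sR,
          conSf, conEf, conSr, conEr,
          vStart, cStart, bStart,
          vIF, cIF, bIFt, bIFi, bIFp,
          vAF, cAF, bAF,
          vT, cT, bTt, bTi, bTp,
          vRS, cRS, bRS,
          vIR, cIR, bIRt, bIRi, bIRq,
          vAR, cAR, bAR,
          vR, cR, bRt, bRi, bRq,
          end_pos, end_val, end_cnt, end_kind, end_idx):
    n = ipar[N_]
    min_i, max_i = ipar[MIN_I], ipar[MAX_I]
    min_ei, max_ei = ipar[MIN_EI], ipar[MAX_EI]
    min_en, max_en = ipar[MIN_EN], ipar[MAX_EN]
    min_et, max_et = ipar[MIN_ET], ipar[MAX_ET]
    min_s, max_s = ipar[MIN_S], ipar[MAX_S]
    min_ig, max_ig = ipar[MIN_IG], ipar[MAX_IG]
    lp_single, lp_multi = fpar[LP_SINGLE], fpar[LP_MULTI]
    lp_cont, lp_term = fpar[LP_CONT], fpar[LP_TERM]
    lp_fwd, lp_rev = fpar[LP_FWD], fpar[LP_REV]
    ig_tlm, ig_lr, ig_l1mr = fpar[IG_TAIL_LOGMASS], fpar[IG_LOG_R], fpar[IG_LOG_1MR]
    reward = fpar[REWARD]

    ns, nd, na, nt = Sf.shape[0], Df.shape[0], Af.shape[0], Tf.shape[0]
    nl, ndr, nar, nr = Lr.shape[0], Dr.shape[0], Ar.shape[0], Rr.shape[0]

    m_end = 1  # end_pos[0] is the origin sentinel (pos 0, val 0)
    end_pos[0] = 0
    end_val[0] = 0.0
    end_cnt[0] = 0
    end_kind[0] = 0
    end_idx[0] = -1

    # running max over tail-region gene ends (positions < s - max_ig)
    tail_ptr = 1
    tail_v = NEG
    tail_idx = -1
    tail_cnt = 0

    iS = iD = iA = iT = iL = iDr = iAr = iR = 0
    while True:
        # pick next event position among the eight candidate streams
        pos = np.int64(1) << 62
        typ = -1
        if iS < ns and Sf[iS] < pos:
            pos = Sf[iS]; typ = 0
        if iL < nl and Lr[iL] < pos:
            pos = Lr[iL]; typ = 4
        if iD < nd and Df[iD] < pos:
            pos = Df[iD]; typ = 1
        if iDr < ndr and Dr[iDr] < pos:
            pos = Dr[iDr]; typ = 5
        if iA < na and Af[iA] < pos:
            pos = Af[iA]; typ = 2
        if iAr < nar and Ar[iAr] < pos:
            pos = Ar[iAr]; typ = 6
        if iT < nt and Tf[iT] < pos:
            pos = Tf[iT]; typ = 3
        if iR < nr and Rr[iR] < pos:
            pos = Rr[iR]; typ = 7
        if typ == -1:
            break

        if typ == 0 or typ == 4:
            # ---- gene start (fwd ATG at s / rev stop-codon at s) ----
            s = pos
            # advance intergenic tail pointer and running max
            while tail_ptr < m_end and end_pos[tail_ptr] < s - max_ig:
                t = end_pos[tail_ptr]
                v = end_val[tail_ptr] - cnf[t] - t * ig_lr
                if v > tail_v or (v == tail_v and end_cnt[tail_ptr] + 1 < tail_cnt):
                    tail_v = v
                    tail_idx = tail_ptr
                    tail_cnt = end_cnt[tail_ptr] + 1
                tail_ptr += 1
            # origin sentinel: leading intergenic scored by survival
            if s <= max_ig:
                sfv = ig_sf[s]
            else:
                sfv = ig_tlm + (s - max_ig - 1) * ig_lr if ig_lr > NEG else NEG
            best = cnf[s] - cnf[0] + sfv
            bcnt = 1 if s > 0 else 0
            bidx = 0
            # histogram-body window over real gene ends
            lo_t = s - max_ig
            if lo_t < 0:
                lo_t = 0
            kk = np.searchsorted(end_pos[:m_end], lo_t)
            if kk == 0:
                kk = 1  # skip sentinel (handled above)
            while kk < m_end and end_pos[kk] <= s - min_ig:
                t = end_pos[kk]
                v = end_val[kk] + (cnf[s] - cnf[t]) + dur_ig[s - t]
                c = end_cnt[kk] + 1
                if v > best or (v == best and c < bcnt):
                    best = v; bcnt = c; bidx = kk
                kk += 1
            # geometric-tail contribution
            if tail_idx >= 0 and ig_lr > NEG:
                v = tail_v + cnf[s] + ig_tlm + ig_l1mr + (s - max_ig - 1) * ig_lr
                if v > best or (v == best and tail_cnt < bcnt):
                    best = v; bcnt = tail_cnt; bidx = tail_idx
            if typ == 0:
                if best > NEG / 2:
                    vStart[iS] = best + lp_fwd + sS[iS]
                    cStart[iS] = bcnt
                    bStart[iS] = bidx
                iS += 1
            else:
                if best > NEG / 2:
                    vRS[iL] = best + lp_rev + sL[iL]
                    cRS[iL] = bcnt
                    bRS[iL] = bidx
                iL += 1

        elif typ == 1:
            # ---- forward donor at d: close initial or internal exon ----
            d = pos
            bl = bar_lo[d]
            for p in range(3):
                best = NEG; bcnt = 0; bt = -1; bi = -1; bp = 0
                m = (d - p) % 3
                lo_stop = last_stop_f[m, d] + 1
                # initial exon from ATG s, class s % 3 == m
                lo = d - max_ei
                if lo < bl:
                    lo = bl
                if lo < lo_stop:
                    lo = lo_stop
                hi = d - min_ei
                kk = np.searchsorted(Sf, lo)
                while kk < ns and Sf[kk] <= hi:
                    s = Sf[kk]
                    if s % 3 == m and vStart[kk] > NEG / 2:
                        g = (3 - s % 3) % 3
                        v = vStart[kk] + (cf[g, d] - cf[g, s]) + dur_ei[d - s] + lp_multi
                        c = cStart[kk] + 1
                        if v > best or (v == best and c < bcnt):
                            best = v; bcnt = c; bt = 0; bi = kk; bp = 0
                    kk += 1
                # internal exon from acceptor e with entry phase p_in
                lo = d - max_en
                if lo < bl:
                    lo = bl
                if lo < lo_stop:
                    lo = lo_stop
                hi = d - min_en
                kk = np.searchsorted(Af, lo)
                while kk < na and Af[kk] <= hi:
                    e = Af[kk]
                    p_in = (p - d + e) % 3  # e == (d + p_in - p) mod 3
                    if vAF[p_in, kk] > NEG / 2:
                        g = (p_in - e) % 3
                        v = vAF[p_in, kk] + (cf[g, d] - cf[g, e]) + dur_en[d - e] + lp_cont
                        c = cAF[p_in, kk] + 1
                        if v > best or (v == best and c < bcnt):
                            best = v; bcnt = c; bt = 1; bi = kk; bp = p_in
                    kk += 1
                if bt >= 0:
                    vIF[p, iD] = best + sD[p, iD]
                    cIF[p, iD] = bcnt
                    bIFt[p, iD] = bt; bIFi[p, iD] = bi; bIFp[p, iD] = bp
            iD += 1

        elif typ == 2:
            # ---- forward acceptor: close intron of phase p ----
            e = pos
            bl = bar_lo[e]
            a1 = codes[e] if e < n else 4
            a2 = codes[e + 1] if e + 1 < n else 4
            for p in range(3):
                best = NEG; bcnt = 0; bi = -1
                lo = e - max_i
                if lo < bl:
                    lo = bl
                hi = e - min_i
                kk = np.searchsorted(Df, lo)
                while kk < nd and Df[kk] <= hi:
                    d = Df[kk]
                    if vIF[p, kk] > NEG / 2:
                        ok = True
                        if p == 1:
                            x = codes[d - 1] if d >= 1 else 4
                            if _is_stop(x, a1, a2):
                                ok = False
                        elif p == 2:
                            x = codes[d - 2] if d >= 2 else 4
                            y = codes[d - 1] if d >= 1 else 4
                            if _is_stop(x, y, a1):
                                ok = False
                        if ok:
                            v = vIF[p, kk] + (cnf[e] - cnf[d]) + dur_i[e - d]
                            if conEf.shape[0] > 0 and _find_con(conEf, conSf, e, d):
                                v += reward
                            c = cIF[p, kk] + 1
                            if v > best or (v == best and c < bcnt):
                                best = v; bcnt = c; bi = kk
                    kk += 1
                if bi >= 0:
                    vAF[p, iA] = best + sA[p, iA]
                    cAF[p, iA] = bcnt
                    bAF[p, iA] = bi
            iA += 1

        elif typ == 3:
            # ---- forward stop end at t: close single or terminal exon ----
            t = pos
            bl = bar_lo[t]
            m = t % 3
            lo_stop = last_stop_f[m, t - 3] + 1 if t >= 3 else 0
            best = NEG; bcnt = 0; bt = -1; bi = -1; bp = 0
            # single-exon gene from ATG s, s % 3 == t % 3
            lo = t - max_s
            if lo < bl:
                lo = bl
            if lo < lo_stop:
                lo = lo_stop
            hi = t - min_s
            kk = np.searchsorted(Sf, lo)
            while kk < ns and Sf[kk] <= hi:
                s = Sf[kk]
                if s % 3 == m and vStart[kk] > NEG / 2:
                    g = (3 - s % 3) % 3
                    v = vStart[kk] + (cf[g, t] - cf[g, s]) + dur_s[t - s] + lp_single
                    c = cStart[kk] + 1
                    if v > best or (v == best and c < bcnt):
                        best = v; bcnt = c; bt = 0; bi = kk; bp = 0
                kk += 1
            # terminal exon from acceptor e (entry phase p), e == (t + p) mod 3
            lo = t - max_et
            if lo < bl:
                lo = bl
            if lo < lo_stop:
                lo = lo_stop
            hi = t - min_et
            kk = np.searchsorted(Af, lo)
            while kk < na and Af[kk] <= hi:
                e = Af[kk]
                p = (e - t) % 3  # e == (t + p) mod 3
                if vAF[p, kk] > NEG / 2:
                    g = (p - e) % 3
                    v = vAF[p, kk] + (cf[g, t] - cf[g, e]) + dur_et[t - e] + lp_term
                    c = cAF[p, kk] + 1
                    if v > best or (v == best and c < bcnt):
                        best = v; bcnt = c; bt = 1; bi = kk; bp = p
                kk += 1
            if bt >= 0:
                vT[iT] = best + sT[iT]
                cT[iT] = bcnt + 1
                bTt[iT] = bt; bTi[iT] = bi; bTp[iT] = bp
                end_pos[m_end] = t
                end_val[m_end] = vT[iT]
                end_cnt[m_end] = cT[iT]
                end_kind[m_end] = 1
                end_idx[m_end] = iT
                m_end += 1
            iT += 1

        elif typ == 5:
            # ---- reverse intron opens at d ("CT"): close terminal/internal ----
            d = pos
            bl = bar_lo[d]
            for q in range(3):  # CDS accumulated left of the intron, mod 3
                best = NEG; bcnt = 0; bt = -1; bi = -1; bq = 0
                m = (d - q) % 3
                g = (d - 1 - q) % 3
                # terminal exon from reverse stop at L (class m); the stop at L
                # is itself the last aligned reverse stop before d
                ls = last_stop_r[m, d]
                lo = d - max_et
                if lo < bl:
                    lo = bl
                if lo < ls:
                    lo = ls
                hi = d - min_et
                kk = np.searchsorted(Lr, lo)
                while kk < nl and Lr[kk] <= hi:
                    L = Lr[kk]
                    if L % 3 == m and L >= ls and vRS[kk] > NEG / 2:
                        v = vRS[kk] + (cr[g, d] - cr[g, L]) + dur_et[d - L] + lp_multi
                        c = cRS[kk] + 1
                        if v > best or (v == best and c < bcnt):
                            best = v; bcnt = c; bt = 0; bi = kk; bq = 0
                    kk += 1
                # internal exon from reverse acceptor-close at e, entry q_in
                lo = d - max_en
                if lo < bl:
                    lo = bl
                if lo < ls + 1:
                    lo = ls + 1
                hi = d - min_en
                kk = np.searchsorted(Ar, lo)
                while kk < nar and Ar[kk] <= hi:
                    e = Ar[kk]
                    q_in = (q - d + e) % 3  # q == (q_in + d - e) mod 3
                    if vAR[q_in, kk] > NEG / 2:
                        v = vAR[q_in, kk] + (cr[g, d] - cr[g, e]) + dur_en[d - e] + lp_cont
                        c = cAR[q_in, kk] + 1
                        if v > best or (v == best and c < bcnt):
                            best = v; bcnt = c; bt = 1; bi = kk; bq = q_in
                    kk += 1
                if bt >= 0:
                    p = (3 - q) % 3
                    vIR[q, iDr] = best + sDr[p, iDr]
                    cIR[q, iDr] = bcnt
                    bIRt[q, iDr] = bt; bIRi[q, iDr] = bi; bIRq[q, iDr] = bq
            iDr += 1

        elif typ == 6:
            # ---- reverse intron closes at e ("AC" end) ----
            e = pos
            bl = bar_lo[e]
            a1 = codes[e] if e < n else 4
            a2 = codes[e + 1] if e + 1 < n else 4
            for q in range(3):
                p = (3 - q) % 3
                best = NEG; bcnt = 0; bi = -1
                lo = e - max_i
                if lo < bl:
                    lo = bl
                hi = e - min_i
                kk = np.searchsorted(Dr, lo)
                while kk < ndr and Dr[kk] <= hi:
                    d = Dr[kk]
                    if vIR[q, kk] > NEG / 2:
                        ok = True
                        if p == 1:
                            x = codes[d - 2] if d >= 2 else 4
                            y = codes[d - 1] if d >= 1 else 4
                            if _is_rstop(x, y, a1):
                                ok = False
                        elif p == 2:
                            x = codes[d - 1] if d >= 1 else 4
                            if _is_rstop(x, a1, a2):
                                ok = False
                        if ok:
                            v = vIR[q, kk] + (cnr[e] - cnr[d]) + dur_i[e - d]
                            if conEr.shape[0] > 0 and _find_con(conEr, conSr, e, d):
                                v += reward
                            c = cIR[q, kk] + 1
                            if v > best or (v == best and c < bcnt):
                                best = v; bcnt = c; bi = kk
                    kk += 1
                if bi >= 0:
                    vAR[q, iAr] = best + sAr[p, iAr]
                    cAR[q, iAr] = bcnt
                    bAR[q, iAr] = bi
            iAr += 1

        else:
            # ---- reverse gene end at R ("CAT" end): close initial/single ----
            R = pos
            bl = bar_lo[R]
            m = R % 3
            g = (R - 1) % 3
            ls = last_stop_r[m, R]
            best = NEG; bcnt = 0; bt = -1; bi = -1; bq = 0
            # single-exon reverse gene from rev stop at L (L % 3 == R % 3)
            lo = R - max_s
            if lo < bl:
                lo = bl
            if lo < ls:
                lo = ls
            hi = R - min_s
            kk = np.searchsorted(Lr, lo)
            while kk < nl and Lr[kk] <= hi:
                L = Lr[kk]
                if L % 3 == m and L >= ls and vRS[kk] > NEG / 2:
                    v = vRS[kk] + (cr[g, R] - cr[g, L]) + dur_s[R - L] + lp_single
                    c = cRS[kk] + 1
                    if v > best or (v == best and c < bcnt):
                        best = v; bcnt = c; bt = 0; bi = kk; bq = 0
                kk += 1
            # initial exon (ends at the CAT) from reverse acceptor-close at e
            lo = R - max_ei
            if lo < bl:
                lo = bl
            if lo < ls + 1:
                lo = ls + 1
            hi = R - min_ei
            kk = np.searchsorted(Ar, lo)
            while kk < nar and Ar[kk] <= hi:
                e = Ar[kk]
                q = (3 - (R - e) % 3) % 3  # entry accumulation: q_out must be 0
                if vAR[q, kk] > NEG / 2:
                    v = vAR[q, kk] + (cr[g, R] - cr[g, e]) + dur_ei[R - e] + lp_term
                    c = cAR[q, kk] + 1
                    if v > best or (v == best and c < bcnt):
                        best = v; bcnt = c; bt = 1; bi = kk; bq = q
                kk += 1
            if bt >= 0:
                vR[iR] = best + sR[iR]
                cR[iR] = bcnt + 1
                bRt[iR] = bt; bRi[iR] = bi; bRq[iR] = bq
                end_pos[m_end] = R
                end_val[m_end] = vR[iR]
                end_cnt[m_end] = cR[iR]
                end_kind[m_end] = 2
                end_idx[m_end] = iR
                m_end += 1
            iR += 1

    return m_end
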