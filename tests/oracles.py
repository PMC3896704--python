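"""Independent brute-force oracles used to validate the package.

These deliberately avoid the implementation's code paths: the sharing
oracle enumerates all inheritance vectors with explicit dense transition
matrices; the segment oracle evaluates every window directly; the LD
oracle recomputes every within-window r2 pair from scratch; the
hypergeometric oracle sums exact rationals.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from pedibd.genotypes import MISSING
from pedibd.pedigree import _topological_order
from pedibd.sharing import haldane_theta


def oracle_sharing(ped, gt, markers):
    """Exhaustive inheritance-vector forward-backward (autosomal)."""
    founders = sorted(ped.founders, key=lambda m: m.person_id)
    nonf = sorted(ped.nonfounders, key=lambda m: m.person_id)
    slot = {}
    for f in founders:
        for h in (0, 1):
            slot[(f.person_id, h)] = len(slot)
    a = len(slot)
    m = 2 * len(nonf)
    S = 1 << m
    bit = {}
    for i, ind in enumerate(nonf):
        bit[(ind.person_id, "p")] = 2 * i
        bit[(ind.person_id, "m")] = 2 * i + 1

    def alleles(v):
        out = {}
        for pid in _topological_order(ped):
            ind = ped.members[pid]
            if ind.is_founder:
                out[pid] = (slot[(pid, 0)], slot[(pid, 1)])
            else:
                fa = out[ind.father_id]
                mo = out[ind.mother_id]
                bp = (v >> bit[(pid, "p")]) & 1
                bm = (v >> bit[(pid, "m")]) & 1
                out[pid] = (fa[bp], mo[bm])
        return out

    AL = [alleles(v) for v in range(S)]
    aff = ped.affected_ids()
    share = np.array(
        [
            any(all(j in AL[v][p] for p in aff) for j in range(a))
            for v in range(S)
        ],
        dtype=float,
    )
    typed = [
        s for s in gt.sample_ids if s in ped.members and ped.members[s].genotyped
    ]
    n_assign = 1 << a
    AB = ((np.arange(n_assign)[:, None] >> np.arange(a)) & 1).astype(np.int8)
    pop = AB.sum(axis=1)

    E = np.empty((len(markers), S))
    for j, mk in enumerate(markers):
        p = min(max(mk.panel_af, 1e-12), 1 - 1e-12)
        prior = p ** pop * (1 - p) ** (a - pop)
        for v in range(S):
            ok = np.ones(n_assign, dtype=bool)
            for t in typed:
                g = gt.calls[j, gt.sample_ids.index(t)]
                if g == MISSING:
                    continue
                i1, i2 = AL[v][t]
                ok &= AB[:, i1] + AB[:, i2] == g
            E[j, v] = prior[ok].sum()
    E[E.sum(axis=1) == 0] = 1.0

    d = np.diff([mk.position_cM for mk in markers]) / 100.0
    th = haldane_theta(d)

    def T(theta):
        M = np.empty((S, S))
        for u in range(S):
            for v in range(S):
                nb = bin(u ^ v).count("1")
                M[u, v] = theta ** nb * (1 - theta) ** (m - nb)
        return M

    Ts = [T(float(t)) for t in th]
    f = np.full(S, 1 / S) * E[0]
    f /= f.sum()
    F = [f]
    for j in range(1, len(markers)):
        f = (F[-1] @ Ts[j - 1]) * E[j]
        f /= f.sum()
        F.append(f)
    B = [np.ones(S)]
    for j in range(len(markers) - 2, -1, -1):
        b = Ts[j] @ (B[0] * E[j + 1])
        b /= b.sum()
        B.insert(0, b)
    out = []
    for j in range(len(markers)):
        post = F[j] * B[j]
        post /= post.sum()
        out.append(float(post @ share))
    return np.array(out)


def oracle_flagged(sharing, threshold, window):
    """Direct window evaluation of the segment rule: marker i qualifies iff
    some window of `window` consecutive markers containing i is entirely
    above threshold (all markers above when the chromosome is shorter)."""
    n = len(sharing)
    above = [s > threshold for s in sharing]
    if n < window:
        return [all(above)] * n
    ok_window = [all(above[s : s + window]) for s in range(n - window + 1)]
    flagged = []
    for i in range(n):
        flagged.append(
            any(
                ok_window[s]
                for s in range(max(0, i - window + 1), min(i, n - window) + 1)
            )
        )
    return flagged


def oracle_ld_prune(calls, chroms, window_size, step, threshold):
    """Independent greedy windowed pruning; returns retained indices."""

    def r2(i, j):
        x, y = calls[i], calls[j]
        ok = (x != MISSING) & (y != MISSING)
        if ok.sum() < 2:
            return None
        x = x[ok].astype(float)
        y = y[ok].astype(float)
        if x.var() == 0 or y.var() == 0:
            return None
        c = np.corrcoef(x, y)[0, 1]
        return c * c

    n = len(calls)
    removed = set()
    spans = []
    s = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[s]:
            spans.append((s, i))
            s = i
    for lo, hi in spans:
        w0 = lo
        while True:
            w1 = min(w0 + window_size, hi)
            changed = True
            while changed:
                changed = False
                live = [i for i in range(w0, w1) if i not in removed]
                for x in range(len(live)):
                    for y in range(x + 1, len(live)):
                        if live[x] in removed or live[y] in removed:
                            continue
                        v = r2(live[x], live[y])
                        if v is not None and v > threshold:
                            removed.add(live[y])
                            changed = True
            if w1 == hi:
                break
            w0 += step
    return [i for i in range(n) if i not in removed]


def oracle_hypergeom_tails(K, n, N):
    """Exact rational upper tails P(X >= k) for all attainable k."""
    lo, hi = max(0, n + K - N), min(K, n)
    denom = comb(N, n)
    pmf = [
        Fraction(comb(K, j) * comb(N - K, n - j), denom) for j in range(lo, hi + 1)
    ]
    tails = {}
    acc = Fraction(0)
    for j in range(hi, lo - 1, -1):
        acc += pmf[j - lo]
        tails[j] = acc
    return tails


def oracle_causal_in_ibd(ped, origins, vix, target, affected, samples):
    """Brute-force descent check: every affected carries the target founder
    allele at locus index ``vix``."""
    at = origins[vix]
    for pid in affected:
        j = samples.index(pid)
        if target not in (at[j, 0], at[j, 1]):
            return False
    return True
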