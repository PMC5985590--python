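"""Backward-in-time coalescent-with-recombination engine.

A Hudson-style ancestral recombination graph over a continuous region
[0, L), with an infinite-sites mutation model. Two modes share the same
machinery:

* neutral: standard coalescent with recombination, continuous
  (exponential) event times in units of generations;
* sweep: a structured coalescent conditioned on a Wright-Fisher
  frequency trajectory of the beneficial allele. During the sweep phase
  time runs in discrete generations; lineages belong to the derived or
  ancestral allelic class, coalesce within their class at a rate scaled
  by the class frequency, and recombination between a lineage's material
  and the selected site moves the piece distal to the selected site into
  a class drawn from the current allele frequency.

Each lineage carries its ancestral material as disjoint segments, each
segment tagged with the bitmask of the samples it is ancestral to.
Mutations are laid on a lineage when it dies (coalesces or splits), as a
Poisson draw over material length x lifetime; a segment whose mask
reaches the full sample set has found its local MRCA and is discarded,
so every emitted mutation is polymorphic in the sample.
"""

from __future__ import annotations

import math
from bisect import bisect_left

import numpy as np

from .core import HaplotypeMatrix


class RescalingError(ValueError):
    pass


class _Lineage:
    __slots__ = ("segs", "klass", "birth", "mat_left", "mat_right", "length")

    def __init__(self, segs, klass, birth):
        self.segs = segs          # list of (left, right, mask)
        self.klass = klass        # 1 = derived, 0 = ancestral
        self.birth = birth
        self.mat_left = segs[0][0]
        self.mat_right = segs[-1][1]
        self.length = sum(r - l for l, r, _ in segs)


def _merge_segments(a, b, full_mask):
    """Union two disjoint-sorted segment lists, OR-ing masks on overlap.

    Segments whose mask becomes the full sample set (local MRCA) are
    dropped. Adjacent pieces with identical masks are re-fused.
    """
    pts = sorted({p for l, r, _ in a for p in (l, r)}
                 | {p for l, r, _ in b for p in (l, r)})
    out = []
    ia = ib = 0
    for i in range(len(pts) - 1):
        lo, hi = pts[i], pts[i + 1]
        mask = 0
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        if ia < len(a) and a[ia][0] <= lo < a[ia][1]:
            mask |= a[ia][2]
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        if ib < len(b) and b[ib][0] <= lo < b[ib][1]:
            mask |= b[ib][2]
        if mask == 0 or mask == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == mask:
            out[-1] = (out[-1][0], hi, mask)
        else:
            out.append((lo, hi, mask))
    return out


class ArgSimulator:
    """One simulation run; collects mutations and builds haplotypes."""

    def __init__(self, n_hap, L, mu, r, N, rng):
        self.n = n_hap
        self.L = float(L)
        self.mu = mu
        self.r = r
        self.N = N
        self.rng = rng
        self.full_mask = (1 << n_hap) - 1
        self.muts = []  # (position float, carrier mask)
        self.t = 0.0
        self.lineages = [
            _Lineage([(0.0, self.L, 1 << i)], 1, 0.0) for i in range(n_hap)
        ]

    # -- mutation bookkeeping -------------------------------------------
    def _emit(self, lin, t_death):
        dt = t_death - lin.birth
        if dt <= 0 or lin.length <= 0 or self.mu == 0:
            return
        k = self.rng.poisson(self.mu * lin.length * dt)
        for _ in range(k):
            u = self.rng.uniform(0.0, lin.length)
            for l, r, m in lin.segs:
                if u < r - l:
                    self.muts.append((l + u, m))
                    break
                u -= r - l

    # -- event primitives -----------------------------------------------
    def _coalesce(self, i, j, t):
        li, lj = self.lineages[i], self.lineages[j]
        self._emit(li, t)
        self._emit(lj, t)
        segs = _merge_segments(li.segs, lj.segs, self.full_mask)
        klass = li.klass
        for idx in sorted((i, j), reverse=True):
            self.lineages.pop(idx)
        if segs:
            self.lineages.append(_Lineage(segs, klass, t))

    def _split(self, idx, bp, t, left_class, right_class):
        lin = self.lineages.pop(idx)
        self._emit(lin, t)
        left, right = [], []
        for l, r, m in lin.segs:
            if r <= bp:
                left.append((l, r, m))
            elif l >= bp:
                right.append((l, r, m))
            else:
                left.append((l, bp, m))
                right.append((bp, r, m))
        if left:
            self.lineages.append(_Lineage(left, left_class, t))
        if right:
            self.lineages.append(_Lineage(right, right_class, t))

    # -- neutral kernel --------------------------------------------------
    def run_neutral(self, duration=None):
        """Standard coalescent-with-recombination for `duration` gens
        (None = until all material reaches its MRCA)."""
        rng = self.rng
        t_stop = None if duration is None else self.t + duration
        while self.lineages:
            k = len(self.lineages)
            spans = [lin.mat_right - lin.mat_left for lin in self.lineages]
            R_rec = self.r * sum(spans)
            R_coal = k * (k - 1) / 2.0 / (2.0 * self.N)
            R = R_rec + R_coal
            if R <= 0:
                break
            dt = rng.exponential(1.0 / R)
            if t_stop is not None and self.t + dt > t_stop:
                self.t = t_stop
                return
            self.t += dt
            if rng.uniform(0, R) < R_coal:
                i, j = rng.choice(k, size=2, replace=False)
                self._coalesce(int(i), int(j), self.t)
            else:
                w = rng.uniform(0, sum(spans))
                idx = 0
                acc = spans[0]
                while acc < w:
                    idx += 1
                    acc += spans[idx]
                lin = self.lineages[idx]
                bp = rng.uniform(lin.mat_left, lin.mat_right)
                self._split(idx, bp, self.t, lin.klass, lin.klass)
        if t_stop is not None:
            self.t = t_stop

    # -- sweep (trajectory) kernel ---------------------------------------
    def run_sweep_phase(self, traj_freqs, sweep_site):
        """Structured coalescent along a backward trajectory.

        traj_freqs: frequency per generation, traj_freqs[0] = 1.0 down to
        1/(2N) then 0; generation g of the phase corresponds to absolute
        time self.t + g. Ends with the forced coalescence of the derived
        class at the origin of the mutation.
        """
        rng = self.rng
        f = np.asarray(traj_freqs, dtype=float)
        g_origin = int(np.nonzero(f > 0)[0][-1])  # generation of single copy
        inv_x = np.where(f > 0, 1.0 / np.maximum(f, 1e-300), 0.0)
        inv_1mx = np.where(f < 1, 1.0 / np.maximum(1.0 - f, 1e-300), 0.0)
        cx = np.concatenate([[0.0], np.cumsum(inv_x[:g_origin + 1])])
        ca = np.concatenate([[0.0], np.cumsum(inv_1mx[:g_origin + 1])])
        t0 = self.t
        g = 0
        while g <= g_origin and self.lineages:
            kd = sum(1 for l in self.lineages if l.klass == 1)
            ka = len(self.lineages) - kd
            ext = [self._ext_span(l, sweep_site) for l in self.lineages]
            A = kd * (kd - 1) / 2.0 / (2.0 * self.N)
            B = ka * (ka - 1) / 2.0 / (2.0 * self.N)
            C = self.r * sum(e[1] - e[0] for e in ext)
            if A == 0 and B == 0 and C == 0:
                break
            target = rng.exponential(1.0)

            def hazard(gg):
                return (A * (cx[gg + 1] - cx[g]) + B * (ca[gg + 1] - ca[g])
                        + C * (gg + 1 - g))

            if hazard(g_origin) < target:
                break  # no event before the allele's origin
            lo, hi = g, g_origin
            while lo < hi:
                mid = (lo + hi) // 2
                if hazard(mid) >= target:
                    hi = mid
                else:
                    lo = mid + 1
            g = lo
            x = f[g]
            rd = A * inv_x[g]
            ra = B * inv_1mx[g]
            u = rng.uniform(0, rd + ra + C)
            self.t = t0 + g
            if u < rd:
                self._coalesce_in_class(1)
            elif u < rd + ra:
                self._coalesce_in_class(0)
            else:
                self._recombine_sweep(ext, sweep_site, x)
        # origin reached: derived lineages descend from the single copy
        self.t = t0 + g_origin
        while True:
            d_idx = [i for i, l in enumerate(self.lineages) if l.klass == 1]
            if len(d_idx) < 2:
                break
            self._coalesce(d_idx[0], d_idx[1], self.t)
        for lin in self.lineages:
            lin.klass = 0

    @staticmethod
    def _ext_span(lin, sweep_site):
        return (min(lin.mat_left, sweep_site), max(lin.mat_right, sweep_site))

    def _coalesce_in_class(self, klass):
        idx = [i for i, l in enumerate(self.lineages) if l.klass == klass]
        i, j = self.rng.choice(len(idx), size=2, replace=False)
        self._coalesce(idx[int(i)], idx[int(j)], self.t)

    def _recombine_sweep(self, ext, sweep_site, x):
        rng = self.rng
        widths = [e[1] - e[0] for e in ext]
        w = rng.uniform(0, sum(widths))
        idx = 0
        acc = widths[0]
        while acc < w:
            idx += 1
            acc += widths[idx]
        lin = self.lineages[idx]
        lo, hi = ext[idx]
        bp = rng.uniform(lo, hi)
        new_class = 1 if rng.random() < x else 0
        if lin.mat_left < bp < lin.mat_right:
            # split; the piece containing the selected site keeps its class
            if sweep_site <= bp:
                self._split(idx, bp, self.t, lin.klass, new_class)
            else:
                self._split(idx, bp, self.t, new_class, lin.klass)
        else:
            # breakpoint between the material and the selected site:
            # the whole lineage is the distal piece and redraws its class
            lin.klass = new_class

    # -- output ----------------------------------------------------------
    def haplotypes(self, region_length) -> HaplotypeMatrix:
        if not self.muts:
            return HaplotypeMatrix(
                alleles=np.zeros((self.n, 0), dtype=np.int8),
                positions=np.zeros(0, dtype=np.int64),
                region_length=int(region_length),
            )
        self.muts.sort()
        positions, masks = [], []
        for pos, mask in self.muts:
            p = int(math.floor(pos)) + 1
            if positions and p == positions[-1]:
                continue  # integer-bp collision: keep the first mutation
            positions.append(p)
            masks.append(mask)
        nbytes = (self.n + 7) // 8
        packed = np.frombuffer(
            b"".join(m.to_bytes(nbytes, "little") for m in masks),
            dtype=np.uint8,
        ).reshape(len(masks), nbytes)
        bits = np.unpackbits(packed, axis=1, bitorder="little")[:, : self.n]
        alleles = np.ascontiguousarray(bits.T).astype(np.int8)
        return HaplotypeMatrix(
            alleles=alleles,
            positions=np.asarray(positions, dtype=np.int64),
            region_length=int(region_length),
        )
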