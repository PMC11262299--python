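"""Two-stage solver for the default synthetic TPC parameters.

Stage 1 finds, per species, curve parameters whose optimum, peak value and
80% breadth match the reference metrics as closely as the family allows
(the optimum gets a heavy weight; near-zero values at the tolerance anchors
are soft targets).  Stage 2 iterates the anchored curve fit on the curve's
own noiseless treatment means until the parameters are a fixed point, so
that optimum-recovery simulations are unbiased; the amplitude is then
rescaled to restore the reference peak speed.

Run from the repo root (takes a couple of minutes):

    python scripts/solve_tpc_params.py

and paste the printed tuples into ``thermoperf/synthetic.py``.  Kept in the
repo so the frozen constants are reproducible.
"""

import numpy as np
from scipy import optimize

from thermoperf.families import get_family
from thermoperf.synthetic import REFERENCE_METRICS
from thermoperf.tpc import ToleranceSummary, fit_family

TREATMENTS = np.array([15.0, 25.0, 30.0, 33.0, 36.0])

_FAMILY = {
    "Crotalus polystictus": "emg_peak",
    "Conopsis lineata": "asym_logistic_peak",
    "Thamnophis melanogaster": "gumbel_peak",
}
TARGETS = {
    sp: (
        _FAMILY[sp], m["ct_min"], m["ct_max"], m["t_o"], m["v_max"],
        m["b80"][0], m["b80"][1],
    )
    for sp, m in REFERENCE_METRICS.items()
}

# For the EMG family, stage 1's best metric-match solution sits in a basin
# whose anchored-fit fixed point is nearly indistinguishable from a Gumbel
# on the 5-treatment design (the 3-parameter competitor then steals the
# AICc selection in recovery simulations).  A recovery pilot identified the
# seed below as a fixed-point basin with both unbiased optimum recovery and
# a clear family-identifiability gap, so stage 2 starts there directly.
STAGE2_OVERRIDE = {
    "emg_peak": (500.0, 36.5, 1.8, 0.35),
}

# stage-1 multistart seeds per family: (location, scale-ish, shape-ish)
SEEDS = {
    "emg_peak": [(mu, s, l) for mu in (36.0, 36.5, 38.0) for s in (1.5, 1.8, 2.5)
                 for l in (0.15, 0.35, 0.5)],
    "asym_logistic_peak": [(c, b, d) for c in (28.0, 30.0, 32.0)
                           for b in (1.5, 2.0, 3.5) for d in (0.4, 0.8, 1.5)],
    "gumbel_peak": [(28.6, s, None) for s in (3.0, 5.0, 8.0)],
}


def pack(fname, loc, scale, shape):
    if fname == "emg_peak":
        return (loc, scale, shape)          # mu, sigma, lam
    if fname == "asym_logistic_peak":
        return (scale, loc, shape)          # b, c, d
    return (loc, scale)                     # mu, sigma


def argmax_of(fam, p, lo, hi):
    g = np.linspace(lo, hi, 20001)
    v = fam(g, p)
    i = int(np.argmax(v))
    return float(g[i]), float(v[i])


def stage1(fname, lo, hi, t_o, v_max, b_lo, b_hi):
    fam = get_family(fname)

    def residuals(x):
        p = (1.0,) + tuple(x)
        tm, vm = argmax_of(fam, p, lo, hi)
        if not np.isfinite(vm) or vm <= 0:
            return [1e6] * 5
        full = (v_max / vm,) + tuple(x)
        lvl = 0.8 * v_max
        return [
            50.0 * (tm - t_o),
            float(fam(np.array(b_lo), full)) - lvl,
            float(fam(np.array(b_hi), full)) - lvl,
            float(fam(np.array(lo), full)),
            float(fam(np.array(hi), full)),
        ]

    best = None
    for loc, scale, shape in SEEDS[fname]:
        x0 = [v for v in pack(fname, loc, scale, shape) if v is not None]
        try:
            sol = optimize.least_squares(residuals, x0, method="lm")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    p = (1.0,) + tuple(best.x)
    _, vm = argmax_of(fam, p, lo, hi)
    return (v_max / vm,) + tuple(best.x)


def stage2(fname, params, lo, hi, v_max, species):
    fam = get_family(fname)
    anchors = ToleranceSummary(species=species, ct_min_mean=lo, ct_max_mean=hi)
    p = params
    for _ in range(12):
        perf = fam(TREATMENTS, p)
        fit = fit_family(
            list(zip(TREATMENTS, perf)), fname, anchors, 33, seed=3, n_starts=6
        )
        if max(abs(np.array(fit.params) - np.array(p))) < 1e-10:
            p = fit.params
            break
        p = fit.params
    _, vm = argmax_of(fam, p, lo, hi)
    return (p[0] * v_max / vm,) + tuple(p[1:])


if __name__ == "__main__":
    for species, (fname, lo, hi, t_o, v_max, b_lo, b_hi) in TARGETS.items():
        fam = get_family(fname)
        p1 = STAGE2_OVERRIDE.get(fname) or stage1(
            fname, lo, hi, t_o, v_max, b_lo, b_hi
        )
        p2 = stage2(fname, p1, lo, hi, v_max, species)
        tm, vm = argmax_of(fam, p2, lo, hi)
        lvl = 0.8 * vm
        f = lambda t: float(fam(np.array(t), p2)) - lvl
        r_lo = optimize.brentq(f, lo, tm) if f(lo) < 0 else lo
        r_hi = optimize.brentq(f, tm, hi) if f(hi) < 0 else hi
        print(f"{species} ({fname}):")
        print("  stage1 =", tuple(round(float(q), 6) for q in p1))
        print("  params =", tuple(round(float(q), 6) for q in p2))
        print(
            f"  implied t_o={tm:.3f} v_max={vm:.3f} "
            f"b80=({r_lo:.3f}, {r_hi:.3f}) "
            f"anchors=({fam(np.array(lo), p2):.4f}, {fam(np.array(hi), p2):.4f})"
        )
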