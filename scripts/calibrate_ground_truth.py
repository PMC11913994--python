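#!/usr/bin/env python
"""Re-derive the committed ground-truth surface coefficients.

The synthetic instrument's five log-quadratic surfaces are pinned to the
effect sizes the optimization campaign is built to recover:

(a) analyte-average peak-height gain of 51% for CID 140 -> 250 kPa at
    IntT 400 degC, IntV 2.5 kV;
(b) analyte-average gain of 32% for IntT 300 -> 400 degC at CID 250 kPa;
(c) weighted joint optimum (weights 2/2/1.5/1/1) at CID 222 kPa,
    IntT 380 degC, IntV at its 2 kV lower bound;
(d) per-analyte marginal optima: PGE2-d4 CID 210-270 kPa and IntT
    360-390 degC; 5-HETE-d8 CID 180-210 kPa with a temperature plateau
    above 390 degC;
(e) sign structure: CID x IntT positive only for LTB4-d4 / 9-HODE-d4,
    IntT x IntV positive only for LXA4-d5, IntV harmful for all (most for
    the polar PGE2-d4 / LXA4-d5).

This script solves (a)-(c) by bounded least squares with (d)/(e) encoded
as bounds and fixed coefficients, then verifies every anchor by direct
grid evaluation.  Its output is what ships in
src/ionopt/data/ground_truth.csv; rerunning it reproduces that table.
"""

import numpy as np
from scipy.optimize import least_squares

ANALYTES = ["PGE2-d4", "LXA4-d5", "LTB4-d4", "9-HODE-d4", "5-HETE-d8"]
W = np.array([2.0, 2.0, 1.5, 1.0, 1.0])
B_VV = np.array([-0.06, -0.06, -0.03, -0.03, -0.03])
B_V = 2 * B_VV  # voltage optimum pinned to coded -1 (2 kV)
B_TV = np.array([0.0, 0.04, 0.0, 0.0, 0.0])
CSTAR, TSTAR = 27.0 / 55.0, 0.6  # coded (222 kPa, 380 degC)

x0 = np.array([
    -0.12, -0.15, 0.80, 0.50,
    -0.12, -0.07, 0.80, 0.85,
    -0.12, -0.08, 0.70, 0.80,
    -0.12, -0.08, 0.70, 0.80,
    -0.22, -0.05, 0.00, 1.30,
    0.08, 0.08,
])
lo = np.array([
    -0.30, -0.30, 0.35, 0.25,
    -0.30, -0.30, 0.20, 0.50,
    -0.30, -0.30, 0.20, 0.40,
    -0.30, -0.30, 0.20, 0.40,
    -0.30, -0.30, -0.25, 1.10,
    0.03, 0.03,
])
hi = np.array([
    -0.05, -0.04, 1.20, 0.75,
    -0.05, -0.04, 1.20, 1.10,
    -0.05, -0.04, 1.20, 1.00,
    -0.05, -0.04, 1.20, 1.00,
    -0.05, -0.04, 0.25, 1.60,
    0.15, 0.15,
])


def unpack(x):
    b_cc, b_tt = x[0:20:4], x[1:20:4]
    c_opt, t_opt = x[2:20:4], x[3:20:4]
    b_ct = np.array([0.0, 0.0, x[20], x[21], 0.0])
    b_c = -2 * b_cc * c_opt - b_ct * t_opt
    b_t = -2 * b_tt * t_opt - b_ct * c_opt
    return b_c, b_t, b_cc, b_tt, b_ct


def residuals(x):
    b_c, b_t, b_cc, b_tt, b_ct = unpack(x)
    r = [
        20 * (np.mean(np.exp(2 * b_c + 2 * b_ct)) - 1.51),
        20 * (np.mean(np.exp(2 * b_t + 2 * b_ct)) - 1.32),
        30 * np.sum(W * (b_c + 2 * b_cc * CSTAR + b_ct * TSTAR)),
        30 * np.sum(W * (b_t + 2 * b_tt * TSTAR + b_ct * CSTAR + B_TV * -1.0)),
    ]
    return np.array(r + list(0.3 * (x - x0)))


def main():
    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    b_c, b_t, b_cc, b_tt, b_ct = unpack(sol.x)
    print("anchor (a) mean CID gain:", np.mean(np.exp(2 * b_c + 2 * b_ct)))
    print("anchor (b) mean IntT gain:", np.mean(np.exp(2 * b_t + 2 * b_ct)))

    cid = np.arange(120, 271, 2)
    intt = np.arange(282, 401, 2)
    intv = np.array([1.8, 2.0, 2.5, 3.0])
    C, T, V = np.meshgrid((cid - 195) / 55, (intt - 350) / 50,
                          (intv - 2.5) / 0.5, indexing="ij")
    obj = sum(
        W[i] * (b_c[i] * C + b_t[i] * T + B_V[i] * V + b_cc[i] * C**2
                + b_tt[i] * T**2 + B_VV[i] * V**2 + b_ct[i] * C * T
                + B_TV[i] * T * V)
        for i in range(5)
    )
    am = np.unravel_index(np.argmax(obj), obj.shape)
    print("anchor (c) weighted argmax:", cid[am[0]], intt[am[1]], intv[am[2]])

    print("\ncoefficient rows (analyte, b_c, b_t, b_v, b_cc, b_tt, b_vv, b_ct, b_tv):")
    for i, a in enumerate(ANALYTES):
        print(f"{a},{b_c[i]:.6f},{b_t[i]:.6f},{B_V[i]:.6f},{b_cc[i]:.6f},"
              f"{b_tt[i]:.6f},{B_VV[i]:.6f},{b_ct[i]:.6f},{B_TV[i]:.6f}")


if __name__ == "__main__":
    main()
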