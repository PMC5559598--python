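"""Independent oracles used by the test suite.

These deliberately re-derive results through different mathematics than the
package (time-domain isochromat Bloch simulation instead of configuration
states; textbook closed forms instead of library fits) so agreement is a
genuine cross-check.
"""

import numpy as np


def bloch_fisp(T1, T2, sched, n_spins=512):
    """Brute-force isochromat Bloch simulation of the FISP sequence.

    ``n_spins`` magnetization vectors with evenly spaced per-TR dephasing
    angles are rotated, relaxed and dephased explicitly; the echo is the
    complex mean transverse magnetization at the echo time (where the net
    gradient moment of the current TR is zero; the unbalanced unit of
    dephasing accrues in the remainder of the TR).
    """
    fa = np.deg2rad(sched.flip_angles_deg)
    tr = sched.repetition_times_ms
    te = sched.echo_time_ms
    theta = 2 * np.pi * np.arange(n_spins) / n_spins
    M = np.zeros((3, n_spins))
    M[2] = -sched.inversion_efficiency
    M[2] = 1 + (M[2] - 1) * np.exp(-sched.inversion_time_ms / T1)

    out = np.empty(len(fa), dtype=complex)
    for i, alpha in enumerate(fa):
        ca, sa = np.cos(alpha), np.sin(alpha)
        my = M[1] * ca - M[2] * sa
        M[2] = M[1] * sa + M[2] * ca
        M[1] = my
        e2, e1 = np.exp(-te / T2), np.exp(-te / T1)
        M[0] *= e2
        M[1] *= e2
        M[2] = 1 + (M[2] - 1) * e1
        out[i] = np.mean(M[0] + 1j * M[1])
        rest = tr[i] - te
        e2, e1 = np.exp(-rest / T2), np.exp(-rest / T1)
        mxy = (M[0] * e2 + 1j * M[1] * e2) * np.exp(1j * theta)
        M[0], M[1] = mxy.real, mxy.imag
        M[2] = 1 + (M[2] - 1) * e1
    return out


def ols_slope_intercept(x, y):
    """Textbook OLS closed form: slope = S_xy / S_xx."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


def two_sample_t(a, b):
    """Equal-variance two-sample t statistic and two-tailed p, closed form."""
    from scipy.stats import t as tdist
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
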