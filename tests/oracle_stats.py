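"""Independent textbook implementations of the statistics toolkit, used only
as oracles in tests.  Written with explicit loops and first-principles
formulas, deliberately avoiding scipy so they share no code with the package.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _var(xs):
    m = _mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def _norm_sf(z):
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def _betacf(a, b, x, maxiter=200, eps=3e-16):
    # continued fraction for the incomplete beta (Numerical Recipes form)
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, maxiter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def _betainc(a, b, x):
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log(1.0 - x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def t_sf(t, df):
    """P(T > t) for Student t with df degrees of freedom."""
    x = df / (df + t * t)
    p = 0.5 * _betainc(df / 2.0, 0.5, x)
    return p if t > 0 else 1.0 - p


def welch_t_oracle(x, y, sided="two"):
    nx, ny = len(x), len(y)
    vx, vy = _var(x), _var(y)
    se2 = vx / nx + vy / ny
    t = (_mean(x) - _mean(y)) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if sided == "two":
        p = 2.0 * t_sf(abs(t), df)
    elif sided == "greater":
        p = t_sf(t, df)
    else:
        p = 1.0 - t_sf(t, df)
    return t, df, p


def student_t_oracle(x, y, sided="two"):
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * _var(x) + (ny - 1) * _var(y)) / df
    t = (_mean(x) - _mean(y)) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    if sided == "two":
        p = 2.0 * t_sf(abs(t), df)
    elif sided == "greater":
        p = t_sf(t, df)
    else:
        p = 1.0 - t_sf(t, df)
    return t, df, p


def cohens_d_oracle(x, y):
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * _var(x) + (ny - 1) * _var(y)) / (nx + ny - 2)
    return (_mean(x) - _mean(y)) / math.sqrt(sp2)


def pearson_r_oracle(x, y):
    n = len(x)
    mx, my = _mean(x), _mean(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, df, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return r, df, 2.0 * t_sf(abs(t), df)


def mann_whitney_oracle(x, y):
    """U by pair enumeration; tie-corrected continuity-corrected normal p."""
    n1, n2 = len(x), len(y)
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    n = n1 + n2
    counts = {}
    for v in list(x) + list(y):
        counts[v] = counts.get(v, 0) + 1
    tie_term = sum(c**3 - c for c in counts.values())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if sigma2 == 0:
        p = 1.0
    else:
        z = max((abs(u - mu) - 0.5), 0.0) / math.sqrt(sigma2)
        p = min(2.0 * _norm_sf(z), 1.0)
    rb = 1.0 - 2.0 * u / (n1 * n2)
    return u, rb, p
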