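"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package's vectorised paths:
likelihoods are computed by explicitly walking the trial sequence with a
dictionary of beta counts, and model-selection quantities by direct
numerical integration.
"""

import math

import numpy as np


def brute_force_nll(model_name, frame, constrained, smoothing="rectifier", alpha=100.0):
    """Trial-by-trial likelihood enumeration with explicit belief tracking.

    ``constrained`` is a dict of native-scale parameters.  Supports the
    same model names as the package.
    """
    joint = model_name.startswith("joint")
    between = model_name == "bayes_between_stim"
    bayes = model_name.startswith("bayes") or joint
    static = model_name.startswith("static_prob")
    wsls = model_name == "wsls"
    bias_all = model_name.endswith("_bias")
    bias_factory = joint

    def softplus(x):
        return math.log1p(math.exp(alpha * x)) / alpha if alpha * x < 700 else x

    def lapse(phi, p):
        if smoothing == "rectifier":
            pos, av = max(phi, 0.0), abs(phi)
        else:
            pos = softplus(phi)
            av = softplus(phi) + softplus(-phi)
        return min(max(pos + (1 - av) * p, 1e-12), 1 - 1e-12)

    df = frame.sort_values(["task", "block", "trial"], kind="stable")
    total = 0.0
    state = {}  # (task, block[, stimulus]) -> [n_succ, n_fail]
    prev = {}  # (task, block) -> (prev_success, prev_loss)
    for _, row in df.iterrows():
        task, block = row["task"], row["block"]
        is_fac = task == "factory"

        if joint:
            tau = constrained["tau_F"] if is_fac else constrained["tau_R"]
        else:
            tau = constrained["tau"]

        if bayes:
            if joint and "mu0_R" in constrained:
                mu = constrained["mu0_F" if is_fac else "mu0_R"]
                s2 = constrained["sigma0_sq_F" if is_fac else "sigma0_sq_R"]
            else:
                mu, s2 = constrained["mu0"], constrained["sigma0_sq"]
            a0 = mu * (1.0 / s2 - 1.0)
            b0 = (1.0 - mu) * (1.0 / s2 - 1.0)
            key = (task, block) if between else (task, block, row["stimulus"])
            ns, nf = state.get(key, (0, 0))
            p_succ = (a0 + ns) / (a0 + b0 + ns + nf)
        elif static:
            p_succ = constrained["p"]
        else:
            p_succ = 1.0

        if task == "robber":
            q_go, q_ng = -row["cost"] + p_succ * row["offer"], 0.0
            if model_name in ("softmax_only", "wsls"):
                q_go = row["offer"] - row["cost"]
        else:
            q_go = -row["cost"] - (1.0 - p_succ) * row["offer"]
            q_ng = -row["offer"]
            if model_name in ("softmax_only", "wsls"):
                q_go = -row["cost"]
        if wsls:
            ps, pl = prev.get((task, block), (0, 0))
            q_go += ps * constrained["gamma_plus"] - pl * constrained["gamma_minus"]

        p_go = 1.0 / (1.0 + math.exp(-(q_go - q_ng) / tau))
        if bias_all:
            p_go = lapse(constrained["phi"], p_go)
        elif bias_factory and is_fac:
            p_go = lapse(constrained["phi_F"], p_go)
        p_go = min(max(p_go, 1e-12), 1 - 1e-12)

        go = int(row["choice"]) == 1
        total -= math.log(p_go if go else 1.0 - p_go)

        if go:
            success = int(row["outcome"]) == 1
            prev[(task, block)] = (int(success), int(not success))
            if bayes:
                ns, nf = state.get(key, (0, 0))
                state[key] = (ns + int(success), nf + int(not success))
        else:
            prev[(task, block)] = (0, 0)
    return total


def dirichlet_xp_2models(alpha, n_grid=200_001):
    """P(r_1 > r_2) under Dirichlet(alpha) by trapezoidal quadrature of the
    Beta marginal on a fine grid."""
    a1, a2 = alpha
    r = np.linspace(0.5, 1.0 - 1e-12, n_grid)
    from scipy.special import betaln

    logpdf = (a1 - 1) * np.log(r) + (a2 - 1) * np.log1p(-r) - betaln(a1, a2)
    return float(np.trapezoid(np.exp(logpdf), r))


def anova_icc21(x):
    """ICC(2,1) from first-principles sums over cells (no mean-square
    shortcuts shared with the implementation)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    mu = x.mean()
    ssr = sum(k * (x[i].mean() - mu) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - mu) ** 2 for j in range(k))
    sst = sum((x[i, j] - mu) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
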