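"""Independent naive replay of the sequence likelihood.

Deliberately written from first principles with plain Python floats and
explicit per-trial loops -- no code shared with the package's likelihood
kernel -- so it can serve as an oracle for equivalence tests.
"""

import math


def _table(transfer, crash, mutual_avoid, scale):
    w, c, m = transfer / scale, crash / scale, mutual_avoid / scale
    # [a1][a2] -> (pi1, pi2), actions 0=avoid 1=rush
    return {
        (0, 0): (m, m),
        (0, 1): (-w, w),
        (1, 0): (w, -w),
        (1, 1): (-c, -c),
    }


def _spow(x, a):
    return math.copysign(abs(x) ** a, x) if x != 0 else 0.0


def naive_player_loglik(
    model,
    params,
    actions,
    transfer=500.0,
    crash=1000.0,
    mutual_avoid=0.0,
    scale=1000.0,
    player=0,
    update_rule="smooth",
):
    """Log-likelihood of one player's choices, replayed step by step.

    ``params`` is a plain tuple; ``actions`` a list of (a_1, a_2) pairs.
    """
    tab = _table(transfer, crash, mutual_avoid, scale)
    other = 1 - player

    def pays(a_own, a_opp):
        joint = (a_own, a_opp) if player == 0 else (a_opp, a_own)
        p = tab[joint]
        return (p[player], p[other])

    # expected current-trial payoffs given own action, uniform over opponent
    e_own = {a: (pays(a, 0)[0] + pays(a, 1)[0]) / 2.0 for a in (0, 1)}
    e_oth = {a: (pays(a, 0)[1] + pays(a, 1)[1]) / 2.0 for a in (0, 1)}

    cum_own = cum_oth = 0.0
    theta = f_self = f_other = 0.0
    logl = 0.0
    for a_pair in actions:
        a_own = a_pair[player]
        a_opp = a_pair[other]
        u = {}
        for a in (0, 1):
            tot_own = cum_own + e_own[a]
            tot_oth = cum_oth + e_oth[a]
            if model == "fs":
                alpha, beta = params
                if tot_own < tot_oth:
                    u[a] = tot_own - alpha * (tot_oth - tot_own)
                else:
                    u[a] = tot_own - beta * (tot_own - tot_oth)
            else:
                alpha, beta, gamma, delta = params
                if model == "cox":
                    weight = theta
                else:
                    weight = 2.0 * (delta * f_other - (1.0 - delta) * f_self)
                u[a] = (_spow(tot_own, alpha) + weight * _spow(tot_oth, alpha)) / alpha
        z = u[0] - u[1]
        # log sigmoid(z) and log sigmoid(-z) in numerically stable form
        if a_own == 0:
            logl += -math.log1p(math.exp(-z)) if z > -700 else z
        else:
            logl += -math.log1p(math.exp(z)) if z < 700 else -z
        k_own = 1.0 - 2.0 * a_own
        k_opp = 1.0 - 2.0 * a_opp
        if model != "fs":
            alpha, beta, gamma, delta = params
            gain = (1.0 - gamma) if update_rule == "smooth" else 1.0
            if model == "cox":
                theta = gamma * theta + gain * delta * k_opp + beta
            else:
                f_self = gamma * f_self + gain * k_own
                f_other = gamma * f_other + gain * k_opp + beta
        po, pt = pays(a_own, a_opp)
        cum_own += po
        cum_oth += pt
    return logl
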