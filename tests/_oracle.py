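"""Independent brute-force reference implementations used only by tests.

Deliberately written in the most literal style possible (explicit state
variables, no shared code with the package) so they can serve as oracles
for the package's expectation engine and likelihood.
"""

import math


def oracle_expectations(records, lr_plus, lr_minus, lr_ext, e0=0.5):
    """Literal trial loop.

    ``records`` is a list of (phase, stimulus, us) tuples in presentation
    order with phase in {"acquisition", "extinction"} and stimulus in
    {"CSP", "CSM", "NA"}.  Returns a list of (e_disc_shown, e_gen) pairs
    sampled before each trial's update; NA trials yield (0.0, 0.0).
    """
    e_csp = e0
    e_csm = e0
    e_gen = e0
    out = []
    for phase, stimulus, us in records:
        if stimulus == "NA":
            out.append((0.0, 0.0))
            continue
        shown = e_csp if stimulus == "CSP" else e_csm
        out.append((shown, e_gen))
        if phase == "extinction":
            rate = lr_ext
        elif us == 1:
            rate = lr_plus
        else:
            rate = lr_minus
        updated = (1.0 - rate) * shown + rate * us
        if stimulus == "CSP":
            e_csp = updated
        else:
            e_csm = updated
        e_gen = (1.0 - rate) * e_gen + rate * us
    return out


def oracle_loglik(y, means, sd):
    """Sum of Normal log-densities, written out longhand."""
    total = 0.0
    for obs, mu in zip(y, means):
        total += (
            -0.5 * math.log(2.0 * math.pi)
            - math.log(sd)
            - 0.5 * ((obs - mu) / sd) ** 2
        )
    return total
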