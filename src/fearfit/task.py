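"""Task design for the differential fear-conditioning startle protocol.

The default design mirrors a two-phase fear-potentiated-startle session:
an acquisition phase with 8 CS+ presentations reinforced by the aversive
air puff at 75% contingency, 8 never-reinforced CS- presentations, and 8
noise-alone (NA) baseline probes, followed (after a rest) by an extinction
phase with 16 presentations of each stimulus type and no US at all.  Each
phase opens with a handful of stabilization startle pulses that settle the
reflex and are excluded from all modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rw import CSM, CSP, NA, PHASE_ACQ, PHASE_EXT, STAB

__all__ = ["TaskDesign", "simulate_trial_sequence"]


@dataclass(frozen=True)
class TaskDesign:
    """Counts and contingency defining one session.

    All per-stimulus counts must be even (downstream blocking averages pairs
    of trials) and at least 2.  The number of reinforced CS+ trials is
    ``round(reinforcement_rate * n_acq_cs_plus)`` (6 of 8 at the default 75%
    contingency).  CS- and NA trials never carry the US.
    """

    n_acq_cs_plus: int = 8
    n_acq_cs_minus: int = 8
    n_acq_na: int = 8
    reinforcement_rate: float = 0.75
    n_ext_per_type: int = 16
    n_stabilization: int = 6

    def __post_init__(self) -> None:
        for field in (
            "n_acq_cs_plus",
            "n_acq_cs_minus",
            "n_acq_na",
            "n_ext_per_type",
        ):
            v = getattr(self, field)
            if v < 2 or v % 2 != 0:
                raise ValueError(
                    f"{field} must be an even count >= 2, got {v}"
                )
        if not (0.0 <= self.reinforcement_rate <= 1.0):
            raise ValueError(
                "reinforcement_rate must be in [0, 1], got "
                f"{self.reinforcement_rate}"
            )
        if self.n_stabilization < 0:
            raise ValueError(
                f"n_stabilization must be >= 0, got {self.n_stabilization}"
            )

    @property
    def n_reinforced(self) -> int:
        return int(round(self.reinforcement_rate * self.n_acq_cs_plus))

    @property
    def n_modeled_trials(self) -> int:
        return (
            self.n_acq_cs_plus
            + self.n_acq_cs_minus
            + self.n_acq_na
            + 3 * self.n_ext_per_type
        )


def _constrained_shuffle(
    labels: list[str], rng: np.random.Generator, max_run: int = 2
) -> list[str]:
    """Shuffle with no more than ``max_run`` consecutive identical labels.

    Rejection sampling; the constraint is loose for the trial mixes used
    here, so a valid order is found quickly.
    """
    arr = np.array(labels)
    for _ in range(10_000):
        perm = rng.permutation(arr)
        run = 1
        ok = True
        for a, b in zip(perm[:-1], perm[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return perm.tolist()
    raise RuntimeError("could not find a constrained trial order")


def simulate_trial_sequence(design: TaskDesign, seed: int) -> pd.DataFrame:
    """Generate one subject's ordered trial stubs.

    Returns a DataFrame with columns ``phase``, ``trial_index`` (1-based
    within phase, stabilization pulses first), ``stimulus`` (CSP / CSM / NA /
    STAB) and ``us``.  Within each phase the modeled trials are pseudo-
    randomly interleaved with at most two consecutive trials of one type,
    and exactly ``design.n_reinforced`` of the acquisition CS+ trials carry
    the US, at random positions.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)

    acq = _constrained_shuffle(
        [CSP] * design.n_acq_cs_plus
        + [CSM] * design.n_acq_cs_minus
        + [NA] * design.n_acq_na,
        rng,
    )
    ext = _constrained_shuffle([CSP, CSM, NA] * design.n_ext_per_type, rng)

    reinforced_pos = set(
        rng.choice(design.n_acq_cs_plus, size=design.n_reinforced, replace=False)
    )

    rows = []
    for phase, order in ((PHASE_ACQ, acq), (PHASE_EXT, ext)):
        idx = 1
        for _ in range(design.n_stabilization):
            rows.append((phase, idx, STAB, 0))
            idx += 1
        csp_seen = 0
        for stim in order:
            us = 0
            if phase == PHASE_ACQ and stim == CSP:
                us = int(csp_seen in reinforced_pos)
                csp_seen += 1
            rows.append((phase, idx, stim, us))
            idx += 1
    return pd.DataFrame(rows, columns=["phase", "trial_index", "stimulus", "us"])
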