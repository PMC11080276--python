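"""Synthetic case-control cohorts.

Two generation modes:

* **marginal-matching** — four study groups (control, T2DM, CAD,
  comorbidity) with the published group sizes (1175/1163/982/504),
  per-group categorical marginals, and per-group continuous summaries;
  within a group, variables are drawn independently, so all dependence
  between risk factors and disease enters through group membership.
* **forward sampling** — ancestral sampling from a declared ground-truth
  BayesNet, used for structure- and parameter-recovery testing.

Continuous variables summarized as mean +/- SD are simulated as normals
truncated at the physical floor 0; the two right-skewed labs (fasting
glucose, triglycerides) are summarized as median (P25, P75) and simulated
log-normally with parameters matched to the median and the quartile ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayesnet import BayesNet
from .codebook import GROUP_COLUMN

_Z75 = stats.norm.ppf(0.75)  # 0.674489...


@dataclass
class GroupProfile:
    """Marginal description of one study group."""

    group: str
    n: int
    categorical_marginals: dict[str, dict[int, float]]
    continuous_normal: dict[str, tuple[float, float]]  # mean, sd
    continuous_lognormal: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # median, p25, p75

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.group}: group size must be positive")
        for var, marg in self.categorical_marginals.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.group}/{var}: marginal sums to {total}, not 1"
                )
        for var, (_, sd) in self.continuous_normal.items():
            if sd < 0:
                raise ValueError(f"{self.group}/{var}: negative sd")


# Per-group observed counts: {variable: {code: (control, T2DM, CAD, comorbidity)}}
_GROUP_NS = (1175, 1163, 982, 504)

_CAT_COUNTS: dict[str, dict[int, tuple[int, int, int, int]]] = {
    "sex": {1: (726, 635, 641, 312), 2: (449, 528, 341, 192)},
    "area": {
        1: (29, 447, 378, 142),
        2: (48, 187, 114, 90),
        3: (1098, 529, 490, 272),
    },
    "education": {
        1: (8, 92, 95, 44),
        2: (259, 936, 812, 418),
        3: (908, 135, 75, 42),
    },
    "marriage": {1: (853, 1099, 949, 482), 2: (322, 64, 33, 22)},
    "occupation": {
        1: (62, 368, 270, 120),
        2: (56, 166, 62, 30),
        3: (785, 137, 123, 61),
        4: (68, 4, 1, 1),
        5: (204, 488, 526, 292),
    },
    "fhx_dm": {0: (1022, 938, 943, 440), 1: (153, 225, 39, 64)},
    "fhx_cad": {0: (1090, 1122, 921, 466), 1: (85, 41, 61, 38)},
    "smoke": {
        1: (933, 866, 654, 357),
        2: (99, 63, 71, 37),
        3: (114, 196, 183, 78),
        4: (29, 38, 74, 32),
    },
    "drink": {
        1: (771, 944, 781, 412),
        2: (354, 133, 108, 50),
        3: (36, 52, 63, 22),
        4: (14, 34, 30, 20),
    },
    # control counts 626 / 897 in the published table conflict with both the
    # group size (column sums 1179 / 1178 vs n=1175) and the printed
    # percentages (52.94% / 76.09% of 1175); corrected to 622 / 894.
    "staple_food": {
        1: (622, 708, 291, 193),
        2: (489, 379, 567, 279),
        3: (64, 76, 124, 32),
    },
    "meat": {
        1: (29, 152, 134, 71),
        2: (483, 486, 497, 255),
        3: (663, 525, 351, 178),
    },
    "vegetable": {
        1: (24, 35, 88, 29),
        2: (434, 521, 499, 252),
        3: (717, 607, 395, 223),
    },
    "fruit": {
        1: (15, 221, 93, 64),
        2: (572, 724, 754, 367),
        3: (556, 203, 123, 64),
        4: (32, 15, 12, 9),
    },
    "sweet": {
        1: (278, 760, 364, 300),
        2: (715, 274, 522, 173),
        3: (162, 87, 78, 23),
        4: (20, 42, 18, 8),
    },
    "exercise": {0: (330, 614, 524, 280), 1: (845, 549, 458, 224)},
    "sleep": {
        1: (40, 130, 199, 106),
        2: (594, 614, 435, 217),
        3: (523, 402, 270, 152),
        4: (18, 17, 78, 29),
    },
    "central_obesity": {0: (894, 719, 646, 287), 1: (281, 444, 336, 217)},
}

# {variable: ((mean, sd) per group)}
_NORMAL_SUMMARIES: dict[str, tuple[tuple[float, float], ...]] = {
    "age": ((40.79, 14.02), (59.98, 12.06), (67.16, 11.75), (67.65, 10.38)),
    "bmi": ((23.43, 3.40), (23.66, 3.98), (22.99, 3.21), (23.60, 3.28)),
    "sbp": ((122.70, 16.11), (135.79, 21.85), (139.34, 21.21), (142.15, 22.04)),
    "dbp": ((74.05, 11.05), (77.52, 12.06), (77.99, 12.10), (77.17, 12.06)),
    # the published comorbidity heart-rate mean "6.55" is corrected to 76.55
    # (physiologic plausibility; see docs/methods.md)
    "heart_rate": (
        (79.49, 12.15),
        (81.44, 12.18),
        (74.12, 12.44),
        (76.55, 11.64),
    ),
    "tc": ((5.20, 1.10), (5.16, 1.47), (4.81, 1.31), (4.63, 1.35)),
    "hdl_c": ((1.37, 0.36), (1.21, 0.47), (1.21, 0.33), (1.14, 0.31)),
    "ldl_c": ((2.67, 1.36), (3.14, 1.28), (2.89, 1.12), (2.68, 1.08)),
}

# {variable: ((median, p25, p75) per group)} — truncated quartile digits in
# the published table restored (see docs/methods.md)
_LOGNORMAL_SUMMARIES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "fbg": (
        (4.87, 4.56, 5.22),
        (7.80, 5.64, 11.40),
        (5.03, 4.57, 5.70),
        (7.61, 5.47, 9.73),
    ),
    "tg": (
        (1.13, 0.81, 1.72),
        (1.47, 1.00, 2.21),
        (1.29, 0.94, 1.81),
        (1.48, 1.04, 2.02),
    ),
}


def reference_profiles(
    overrides: dict | None = None,
) -> dict[str, GroupProfile]:
    """Built-in group profiles of the four study groups.

    ``overrides`` may replace any continuous summary, keyed
    ``(group, variable)`` -> (mean, sd) or (median, p25, p75), e.g. to undo
    the typo corrections documented in docs/methods.md.
    """
    from .codebook import GROUPS

    overrides = overrides or {}
    profiles = {}
    for gi, group in enumerate(GROUPS):
        n = _GROUP_NS[gi]
        cat = {
            var: {code: counts[gi] / n for code, counts in states.items()}
            for var, states in _CAT_COUNTS.items()
        }
        normal = {
            var: overrides.get((group, var), summaries[gi])
            for var, summaries in _NORMAL_SUMMARIES.items()
        }
        lognormal = {
            var: overrides.get((group, var), summaries[gi])
            for var, summaries in _LOGNORMAL_SUMMARIES.items()
        }
        profiles[group] = GroupProfile(
            group=group,
            n=n,
            categorical_marginals=cat,
            continuous_normal=normal,
            continuous_lognormal=lognormal,
        )
    return profiles


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_case_control(
    profiles: dict[str, GroupProfile], seed: int
) -> pd.DataFrame:
    """Draw a full case-control cohort matching the group profiles.

    Group sizes are honored exactly; within a group every variable is drawn
    independently from its marginal/summary.  Deterministic for a fixed seed.
    """
    frames = []
    for gi, (group, prof) in enumerate(sorted(profiles.items())):
        cols: dict[str, np.ndarray] = {GROUP_COLUMN: np.repeat(group, prof.n)}
        for vi, (var, marg) in enumerate(
            sorted(prof.categorical_marginals.items())
        ):
            rng = _substream(seed, 1, gi, vi)
            codes = np.array(sorted(marg))
            p = np.array([marg[c] for c in codes])
            cols[var] = rng.choice(codes, size=prof.n, p=p / p.sum())
        for vi, (var, (mean, sd)) in enumerate(
            sorted(prof.continuous_normal.items())
        ):
            rng = _substream(seed, 2, gi, vi)
            if sd == 0:
                cols[var] = np.full(prof.n, mean)
                continue
            a = (0.0 - mean) / sd  # physical floor at 0
            draw = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
            cols[var] = np.round(draw.rvs(size=prof.n, random_state=rng), 2)
        for vi, (var, (median, p25, p75)) in enumerate(
            sorted(prof.continuous_lognormal.items())
        ):
            rng = _substream(seed, 3, gi, vi)
            mu = np.log(median)
            sigma = np.log(p75 / p25) / (2 * _Z75)
            cols[var] = np.round(rng.lognormal(mu, sigma, size=prof.n), 2)
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    # stable, seed-dependent row shuffle so groups are interleaved
    order = _substream(seed, 0).permutation(len(out))
    return out.iloc[order].reset_index(drop=True)


def generate_from_bn(
    truth: BayesNet, n: int, seed: int
) -> pd.DataFrame:
    """Forward (ancestral) sampling of ``n`` records from a ground-truth net."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    order = truth.dag.topological_order()
    data: dict[str, np.ndarray] = {}
    for node in order:
        parents = truth.dag.parents(node)
        cpt = truth.cpts[node]
        states = np.asarray(truth.states[node])
        if not parents:
            idx = rng.choice(len(states), size=n, p=cpt.table[0])
        else:
            # row index of each record's parent configuration
            rows = np.zeros(n, dtype=int)
            for p in parents:
                p_states = list(truth.states[p])
                codes = np.array(
                    [p_states.index(v) for v in data[p]], dtype=int
                )
                rows = rows * truth.card(p) + codes
            u = rng.random(n)
            cum = np.cumsum(cpt.table, axis=1)
            idx = (u[:, None] > cum[rows]).sum(axis=1)
        data[node] = states[idx]
    return pd.DataFrame({node: data[node] for node in truth.dag.nodes})
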