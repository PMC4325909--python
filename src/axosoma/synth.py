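"""Synthetic alpha-motoneuron morphologies.

Generates statistically realistic somato-dendritic trees matching target
morphometrics of adult cat lumbar alpha motoneurons: soma diameter in the
50-120 um range, around 8-16 primary (stem) dendrites, total dendritic
surface of 1.4-8 x 10^5 um^2 and mean terminal path distances of roughly
450-1180 um.  The growth model is deliberately simple: recursive branching
with exponentially distributed segment lengths, child diameters drawn from a
Rall-type power rule with multiplicative noise, gentle taper, and a terminal
path-distance budget per trunk.  A final global diameter rescale of the
dendrites (topology preserved, floor respected) hits the requested total
surface.

The generator is fully deterministic given its integer seed and never touches
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .morphology import Morphology, Section, morphometrics

__all__ = ["SynthMorphParams", "GenerationError", "generate", "generate_pool",
           "TABLE1_MEAN", "TABLE1_SD"]

# Pool statistics of the 14 imported cat motoneuron reconstructions
# (mean / SD rows of the morphometric summary): soma diameter (um),
# primary-dendrite count, dendritic surface (um^2), mean terminal path
# distance (um).
TABLE1_MEAN = {
    "soma_diameter": 79.20,
    "n_primary": 11,
    "dendrite_surface": 454_682.0,
    "mean_terminal_distance": 913.27,
}
TABLE1_SD = {
    "soma_diameter": 23.55,
    "n_primary": 2.40,
    "dendrite_surface": 241_558.0,
    "mean_terminal_distance": 254.13,
}

DIAMETER_FLOOR = 0.5  # um; growth stops below this


class GenerationError(RuntimeError):
    """Targets unreachable within the configured retry budget."""


@dataclass(frozen=True)
class SynthMorphParams:
    """Targets and growth controls for one synthetic morphology."""

    seed: int = 0
    soma_diameter: float = TABLE1_MEAN["soma_diameter"]  # um
    n_primary: int = TABLE1_MEAN["n_primary"]
    target_dendrite_surface: float = TABLE1_MEAN["dendrite_surface"]  # um^2
    mean_terminal_distance: float = TABLE1_MEAN["mean_terminal_distance"]  # um
    branch_prob: float = 0.004  # per um of grown neurite
    taper: float = 0.2  # fractional diameter loss per 100 um
    rall_exponent: float = 1.5  # Rall power-rule exponent e
    trunk_diameter: float | None = None  # um; default scales with soma size
    mean_segment_length: float = 80.0  # um, exponential mean

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        for name in ("soma_diameter", "target_dendrite_surface",
                     "mean_terminal_distance", "mean_segment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.branch_prob < 0:
            raise ValueError("branch_prob must be >= 0")


def _rand_direction(rng: np.random.Generator, prev: np.ndarray | None) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    if prev is not None:
        # persistence: keep growing roughly outward
        v = 0.7 * prev + 0.3 * v
        v /= np.linalg.norm(v)
    return v


def generate(params: SynthMorphParams) -> Morphology:
    """Grow one labelled morphology hitting the requested morphometrics.

    The returned tree has a two-cylinder soma plus ``n_primary`` branched
    dendritic trunks; its measured soma diameter, dendritic surface and mean
    terminal distance fall within 15% of the targets (typically much closer).
    Deterministic given ``params.seed``.
    """
    last_err = None
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, attempt]))
        try:
            return _grow(params, rng)
        except GenerationError as exc:  # retry with fresh stream
            last_err = exc
    raise GenerationError(f"could not meet targets after retries: {last_err}")


def _grow(params: SynthMorphParams, rng: np.random.Generator) -> Morphology:
    d_soma = params.soma_diameter
    soma_pts = np.array(
        [[0.0, -d_soma / 2.0, 0.0, d_soma],
         [0.0, 0.0, 0.0, d_soma],
         [0.0, d_soma / 2.0, 0.0, d_soma]]
    )
    sections: list[Section] = [Section(points=soma_pts, parent=None,
                                       region="soma", nseg=2)]

    trunk_d = params.trunk_diameter
    if trunk_d is None:
        # stem diameters of cat motoneurons scale with soma size; the pool
        # mean sum of primary diameters (~99 um over ~11 stems) implies ~9 um
        trunk_d = max(4.0, 0.11 * d_soma)

    # Each trunk gets a terminal path-distance budget jittered around the
    # target so the tree has realistic spread in tip distances.
    budgets = params.mean_terminal_distance * rng.uniform(0.85, 1.15,
                                                          params.n_primary)

    # stack of (parent_section_index, start_xyz, direction, diameter,
    #           remaining_budget)
    stack: list[tuple[int, np.ndarray, np.ndarray, float, float]] = []
    for k in range(params.n_primary):
        direction = _rand_direction(rng, None)
        start = direction * (d_soma / 2.0)
        stack.append((0, start, direction, trunk_d, float(budgets[k])))

    guard = 0
    while stack:
        guard += 1
        if guard > 100_000:
            raise GenerationError("runaway growth")
        parent_idx, start, direction, diam, budget = stack.pop()
        if budget <= 0:
            continue
        diam = max(diam, DIAMETER_FLOOR)
        # section length: exponential, capped by the remaining budget
        seg_len = float(rng.exponential(params.mean_segment_length))
        seg_len = min(max(seg_len, 10.0), budget)
        d_end = max(DIAMETER_FLOOR, diam * (1.0 - params.taper * seg_len / 100.0))
        end = start + direction * seg_len
        pts = np.array([
            [*start, diam],
            [*(start + direction * seg_len / 2.0), 0.5 * (diam + d_end)],
            [*end, d_end],
        ])
        sec = Section(points=pts, parent=parent_idx,
                      parent_pos=0.5 if parent_idx == 0 else 1.0,
                      region="dendrite")
        sections.append(sec)
        idx = len(sections) - 1
        remaining = budget - seg_len
        if remaining <= 0:
            continue
        # growth continues to the path-distance budget (diameter clamped at
        # the floor); only branching stops at the floor
        branch_here = (d_end > DIAMETER_FLOOR
                       and rng.random() < 1.0 - math.exp(-params.branch_prob * seg_len))
        if branch_here:
            # Rall power rule for two equal daughters, with noise
            d_child = (d_end ** params.rall_exponent / 2.0) ** (1.0 / params.rall_exponent)
            for _ in range(2):
                dc = d_child * rng.uniform(0.8, 1.2)
                stack.append((idx, end, _rand_direction(rng, direction), dc,
                              remaining))
        else:
            stack.append((idx, end, _rand_direction(rng, direction), d_end,
                          remaining))

    m = Morphology(sections=sections, soma_sections=[0],
                   metadata={"source": f"synthetic(seed={params.seed})",
                             "units": "um"})

    # global dendrite diameter rescale to hit the surface target
    mm = morphometrics(m)
    if mm.dendrite_surface <= 0:
        raise GenerationError("no dendritic surface grown")
    scale = params.target_dendrite_surface / mm.dendrite_surface
    if scale < 0.05 or scale > 20.0:
        raise GenerationError(
            f"surface target needs diameter rescale x{scale:.2f}, out of range")
    for sec in m.sections:
        if sec.region == "dendrite":
            sec.points[:, 3] = np.maximum(DIAMETER_FLOOR, sec.points[:, 3] * scale)

    mm = morphometrics(m)
    for name, target, got in [
        ("soma_diameter", params.soma_diameter, mm.soma_diameter),
        ("dendrite_surface", params.target_dendrite_surface, mm.dendrite_surface),
        ("mean_terminal_distance", params.mean_terminal_distance,
         mm.mean_terminal_distance),
    ]:
        if abs(got - target) > 0.15 * target:
            raise GenerationError(
                f"{name}: got {got:.1f}, target {target:.1f} (>15% off)")
    return m


def generate_pool(
    n: int,
    base: SynthMorphParams,
    variability: float = 0.0,
    seed: int = 0,
) -> list[Morphology]:
    """Generate ``n`` morphologies with parameters jittered by +-variability.

    Each cell's soma diameter, surface target and terminal-distance target are
    multiplied by an independent uniform factor in ``[1 - v, 1 + v]``; the
    primary-dendrite count is jittered likewise and rounded.  Reproducible
    given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if variability == 0.0:
        rngs = [np.random.SeedSequence([seed, i]) for i in range(n)]
        out = []
        for i in range(n):
            cell_seed = int(np.random.default_rng(rngs[i]).integers(0, 2**31 - 1))
            out.append(generate(replace(base, seed=base.seed if n == 1 else cell_seed)))
        return out
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        f = rng.uniform(1.0 - variability, 1.0 + variability, size=4)
        p = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            soma_diameter=base.soma_diameter * f[0],
            n_primary=max(1, round(base.n_primary * f[1])),
            target_dendrite_surface=base.target_dendrite_surface * f[2],
            mean_terminal_distance=base.mean_terminal_distance * f[3],
        )
        out.append(generate(p))
    return out
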