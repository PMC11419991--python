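"""Synthetic multi-run connectome datasets with planted archetype structure.

Emulates the structure of a multi-subject, multi-run resting-state study:
S subjects x R runs of N x N Fisher-z connectomes whose profiles fall into
K archetypes arranged on a 2-D grid. An X factor modulates connectivity
within an "anterior" node block and a Y factor modulates a "posterior"
block, so grid position maps onto distinct connectivity signatures. Runs of
the same subject tend to share that subject's modal archetype with a
configurable consistency probability. Behaviors are generated per subject
with known coding: X main effect, Y main effect, pure X:Y interaction
(the XOR/degenerate pattern), or null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ConnectomeSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_partition",
    "generate_templates",
    "simulate_dataset",
    "simulate_behavior",
    "DEFAULT_CODING_MAP",
]

#: Default behavior battery: one behavior per coding pattern, mirroring the
#: observation that grid dimensions code distinct trait families (cognitive
#: scores on X, delay discounting on Y, socioemotional traits such as
#: loneliness on the X:Y interaction).
DEFAULT_CODING_MAP = {
    "fluid_intelligence": "x",
    "discounting": "y",
    "loneliness": "interaction",
    "null_trait": "null",
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic connectome study.

    Defaults describe the reference synthetic condition: 200 subjects with
    4 runs each, 90-node connectomes, a 2x2 archetype grid, a within-block
    effect of 0.75 z-units per grid level over 0.5 z-units of edge noise
    (effect/noise = 1.5), and run consistency 0.8.

    Parameters
    ----------
    block_effect : float
        Fisher-z units added to within-block connectivity per grid level.
    noise_sd : float
        Standard deviation (z-units) of i.i.d. symmetric edge noise; 0 is
        allowed as the noiseless degenerate case.
    run_consistency : float
        Probability rho that a run inherits its subject's modal archetype;
        with probability 1-rho the run's archetype is resampled uniformly
        over all grid cells (so the empirical match rate converges to
        rho + (1-rho)/K).
    baseline : float
        Constant off-diagonal connectivity shared by all templates.
    """

    n_subjects: int = 200
    n_runs: int = 4
    n_nodes: int = 90
    grid_dims: tuple = (2, 2)
    block_effect: float = 0.75
    noise_sd: float = 0.5
    run_consistency: float = 0.8
    baseline: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 8:
            raise ValueError("n_nodes must be >= 8")
        dx, dy = self.grid_dims
        if dx < 1 or dy < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0 <= self.run_consistency <= 1:
            raise ValueError("run_consistency must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ValueError("n_subjects and n_runs must be >= 1")

    @property
    def n_archetypes(self) -> int:
        return self.grid_dims[0] * self.grid_dims[1]


@dataclass
class GroundTruth:
    """Planted assignments and behavior coding of a synthetic dataset."""

    archetype_per_obs: np.ndarray  # (n_obs, 2) grid cell (x, y) per (subject, run)
    subject_modal_archetype: np.ndarray  # (n_subjects, 2)
    grid_dims: tuple
    subject_ids: np.ndarray = None
    run_ids: np.ndarray = None
    coding_map: dict = field(default_factory=dict)

    def __post_init__(self):
        dx, dy = self.grid_dims
        cells = np.asarray(self.archetype_per_obs)
        if cells.size and not (
            np.all((cells[:, 0] >= 1) & (cells[:, 0] <= dx))
            and np.all((cells[:, 1] >= 1) & (cells[:, 1] <= dy))
        ):
            raise ValueError("archetype_per_obs contains off-grid cells")

    def labels_per_obs(self) -> np.ndarray:
        """Flat archetype label per observation: 1 + (x-1) + Dx*(y-1)."""
        dx = self.grid_dims[0]
        c = self.archetype_per_obs
        return 1 + (c[:, 0] - 1) + dx * (c[:, 1] - 1)


def default_partition(n_nodes: int) -> np.ndarray:
    """Fixed node->block assignment used by the generator.

    The first ``ceil(N/3)`` nodes form the "anterior" block (modulated by
    the X grid factor), the next ``ceil(N/3)`` the "posterior" block
    (modulated by Y); remaining nodes are unmodulated background.
    """
    third = -(-n_nodes // 3)
    blocks = np.full(n_nodes, "background", dtype=object)
    blocks[:third] = "anterior"
    blocks[third : min(2 * third, n_nodes)] = "posterior"
    return blocks


def _block_mask(blocks: np.ndarray, name: str) -> np.ndarray:
    """Off-diagonal within-block mask for one block."""
    members = blocks == name
    mask = np.outer(members, members)
    np.fill_diagonal(mask, False)
    return mask


def generate_templates(cfg: SynthConfig, partition=None) -> np.ndarray:
    """Build one N x N template matrix per grid cell.

    Returns an array of shape ``(Dx, Dy, N, N)``; ``templates[x-1, y-1]``
    is the noiseless connectome of archetype (x, y). The X level adds
    ``(x-1) * block_effect`` to every anterior within-block edge and the Y
    level adds ``(y-1) * block_effect`` to every posterior within-block
    edge, on top of a constant baseline. Templates are symmetric with zero
    diagonal.
    """
    n = cfg.n_nodes
    if partition is None:
        partition = default_partition(n)
    if isinstance(partition, dict):
        blocks = np.full(n, "background", dtype=object)
        for node, blk in partition.items():
            if not 0 <= int(node) < n:
                raise ValueError(f"partition references unknown node {node}")
            blocks[int(node)] = blk
    else:
        blocks = np.asarray(partition, dtype=object)
        if blocks.shape != (n,):
            raise ValueError("partition must assign a block to each node")
    anterior = _block_mask(blocks, "anterior")
    posterior = _block_mask(blocks, "posterior")
    dx, dy = cfg.grid_dims
    base = np.full((n, n), cfg.baseline)
    np.fill_diagonal(base, 0.0)
    templates = np.empty((dx, dy, n, n))
    for x in range(1, dx + 1):
        for y in range(1, dy + 1):
            t = base.copy()
            t[anterior] += (x - 1) * cfg.block_effect
            t[posterior] += (y - 1) * cfg.block_effect
            templates[x - 1, y - 1] = t
    return templates


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    noise = np.zeros((n, n))
    noise[iu] = rng.normal(0.0, sd, size=len(iu[0])) if sd > 0 else 0.0
    return noise + noise.T


def simulate_dataset(cfg: SynthConfig, templates=None, partition=None):
    """Simulate the full multi-run connectome dataset.

    Each subject draws a modal archetype uniformly over the grid; each run
    independently keeps it with probability ``run_consistency`` and
    otherwise resamples uniformly over all cells. Each observation is its
    archetype's template plus symmetric Gaussian edge noise. Bit-identical
    under a fixed ``cfg.seed``.

    Returns
    -------
    (ConnectomeSet, GroundTruth)
    """
    if templates is None:
        templates = generate_templates(cfg, partition)
    rng = np.random.default_rng(cfg.seed)
    dx, dy = cfg.grid_dims
    k = dx * dy
    n_obs = cfg.n_subjects * cfg.n_runs

    modal_flat = rng.integers(0, k, size=cfg.n_subjects)
    keep = rng.random((cfg.n_subjects, cfg.n_runs)) < cfg.run_consistency
    resampled = rng.integers(0, k, size=(cfg.n_subjects, cfg.n_runs))
    flat = np.where(keep, modal_flat[:, None], resampled)

    def to_xy(f):
        return np.stack([1 + (f % dx), 1 + (f // dx)], axis=-1)

    cells = to_xy(flat.reshape(-1))
    modal_cells = to_xy(modal_flat)

    matrices = np.empty((n_obs, cfg.n_nodes, cfg.n_nodes))
    for i, (x, y) in enumerate(cells):
        matrices[i] = templates[x - 1, y - 1] + _symmetric_noise(
            rng, cfg.n_nodes, cfg.noise_sd
        )

    subject_ids = np.repeat(
        [f"sub-{s:04d}" for s in range(1, cfg.n_subjects + 1)], cfg.n_runs
    )
    run_ids = np.tile(np.arange(1, cfg.n_runs + 1), cfg.n_subjects)
    blocks = default_partition(cfg.n_nodes) if partition is None else partition
    network_map = None
    if not isinstance(blocks, dict):
        network_map = {f"node_{i:03d}": str(b) for i, b in enumerate(np.asarray(blocks))}
    cs = ConnectomeSet(
        matrices=matrices,
        subject_ids=subject_ids,
        run_ids=run_ids,
        network_map=network_map,
    )
    truth = GroundTruth(
        archetype_per_obs=cells,
        subject_modal_archetype=modal_cells,
        grid_dims=cfg.grid_dims,
        subject_ids=subject_ids,
        run_ids=run_ids,
    )
    return cs, truth


def simulate_behavior(
    truth: GroundTruth,
    effect_size: float = 0.8,
    noise_sd: float = 1.0,
    coding_map: dict = None,
    seed=0,
    baseline: float = 50.0,
) -> pd.DataFrame:
    """Generate per-subject behavior scores with known coding.

    Each subject's score is ``baseline + d * sigma * g(modal x, y) + noise``
    where ``g`` is a binary indicator determined by the behavior's coding
    (with ``noise_sd=0`` the standardized effect is applied on a unit
    scale, giving noiseless group patterns):

    - ``"x"``: high iff the modal x coordinate is at the last grid level;
    - ``"y"``: high iff the modal y coordinate is at the last level;
    - ``"interaction"``: XOR pattern, high iff exactly one of (x, y) is at
      its last level — structurally different archetypes share the same
      elevated outcome (degenerate coding);
    - ``"null"``: pure noise.

    Scores are constant per subject (behavior is a trait, not a per-run
    measurement). The realized coding is recorded in ``truth.coding_map``.

    Returns a DataFrame with ``subject_id`` plus one column per behavior.
    """
    if coding_map is None:
        coding_map = dict(DEFAULT_CODING_MAP)
    dx, dy = truth.grid_dims
    rng = np.random.default_rng(seed)
    modal = truth.subject_modal_archetype
    n = modal.shape[0]
    subject_ids = (
        pd.unique(truth.subject_ids)
        if truth.subject_ids is not None
        else np.array([f"sub-{s:04d}" for s in range(1, n + 1)])
    )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sigma_eff = noise_sd if noise_sd > 0 else 1.0
    out = {"subject_id": subject_ids}
    for name, coding in coding_map.items():
        if coding == "x":
            g = (modal[:, 0] == dx).astype(float)
        elif coding == "y":
            g = (modal[:, 1] == dy).astype(float)
        elif coding == "interaction":
            if dx < 2 or dy < 2:
                raise ValueError(
                    "interaction-coded behavior requires a grid of at least 2x2"
                )
            g = ((modal[:, 0] == dx) ^ (modal[:, 1] == dy)).astype(float)
        elif coding == "null":
            g = np.zeros(n)
        else:
            raise ValueError(f"unknown coding {coding!r} for behavior {name!r}")
        noise = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        out[name] = baseline + effect_size * sigma_eff * g + noise
    truth.coding_map = dict(coding_map)
    return pd.DataFrame(out)
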