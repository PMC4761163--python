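import numpy as np
import pytest

from phyloniche.geodata import EnvStack, OccurrenceSet
from phyloniche.synthetic import NicheSpec, SimConfig, simulate_env_stack, simulate_tree


def make_stack(arrays: dict[str, np.ndarray], cellsize: float = 1.0,
               mask: np.ndarray | None = None) -> EnvStack:
    """Build an EnvStack directly from per-variable arrays (row 0 = north)."""
    grids = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
    shape = next(iter(grids.values())).shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    grids = {k: np.where(mask, g, np.nan) for k, g in grids.items()}
    return EnvStack(list(grids), grids, 0.0, 0.0, cellsize, mask)


def occ_at_cells(stack: EnvStack, cells: list[tuple[int, int]], species="sp") -> OccurrenceSet:
    """Occurrences at the centers of the given (row, col) cells."""
    pts = [stack.cell_center(r, c) for r, c in cells]
    return OccurrenceSet(species, np.array(pts))


@pytest.fixture(scope="session")
def small_scene():
    """A 15×15 landscape with two gradient-like variables and a 6-tip tree."""
    cfg = SimConfig(
        n_rows=15, n_cols=15, variables=("bio4", "bio6"),
        ranges={"bio4": (13.7, 41.4), "bio6": (7.0, 18.9)},
        autocorr_length=2.0, n_tips=6, seed=42,
    )
    stack = simulate_env_stack(cfg)
    tree = simulate_tree(cfg.n_tips, seed=cfg.seed)
    return cfg, stack, tree
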