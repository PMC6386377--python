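import numpy as np
import pytest

from morphoquant.engine import SuggestionContext, default_recipe
from morphoquant.synth import (SyntheticSpec, generate_particle_image,
                               generate_touching_pair)


@pytest.fixture(scope="session")
def fluorescence_context():
    return SuggestionContext("fluorescence", "mammalian_cells")


@pytest.fixture(scope="session")
def fluorescence_recipe(fluorescence_context):
    return default_recipe(fluorescence_context)


@pytest.fixture(scope="session")
def disjoint_image():
    """Noisy synthetic image with 25 disjoint particles + its ground truth."""
    spec = SyntheticSpec(width=256, height=256, n_particles=25,
                         axis_range=(4, 9), noise_model="gaussian", seed=42)
    return generate_particle_image(spec)


@pytest.fixture(scope="session")
def touching_pair():
    """Two overlapping disks (radius 15, centre gap 20), noiseless."""
    return generate_touching_pair(radius=15, centre_gap=20, seed=3)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Independent connected-component counter (BFS flood fill)."""
    mask = np.asarray(mask, bool)
    visited = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not visited[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                visited[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and not visited[rr, cc]):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
    return count


def brute_force_moment_ellipse(mask: np.ndarray):
    """Axes of the moment-equivalent ellipse from raw pixel-centre moments.

    Independent of skimage: builds the central second-moment tensor of the
    foreground pixel-centre point set and returns (major, minor) full axis
    lengths 4*sqrt(eigenvalues).
    """
    rows, cols = np.nonzero(np.asarray(mask, bool))
    n = rows.size
    r0, c0 = rows.mean(), cols.mean()
    mrr = ((rows - r0) ** 2).mean()
    mcc = ((cols - c0) ** 2).mean()
    mrc = ((rows - r0) * (cols - c0)).mean()
    eig = np.linalg.eigvalsh(np.array([[mrr, mrc], [mrc, mcc]]))
    return 4.0 * np.sqrt(eig[1]), 4.0 * np.sqrt(eig[0])
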