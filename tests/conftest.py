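import numpy as np
import pytest

from scresample import simulate
from scresample.containers import CellMatrix


def naive_weight_ladder(Z: np.ndarray, alpha: float, n_bins: int):
    """Brute-force reimplementation of the AR weight ladder.

    Loops explicitly over dimensions, samples and bins; independent of the
    vectorized implementation it cross-checks.
    """
    Z = np.asarray(Z, dtype=float)
    n, k_dims = Z.shape
    p_star = np.zeros((k_dims, n))
    for k in range(k_dims):
        col = Z[:, k]
        lo, hi = col.min(), col.max()
        if lo == hi:
            raw = np.full(n, 1.0)
        else:
            width = (hi - lo) / n_bins
            raw = np.zeros(n)
            for i in range(n):
                b = int((col[i] - lo) / width)
                if b >= n_bins:
                    b = n_bins - 1
                left, right = lo + b * width, lo + (b + 1) * width
                count = 0
                for j in range(n):
                    inside = left <= col[j] < right or (
                        b == n_bins - 1 and left <= col[j] <= hi)
                    count += inside
                raw[i] = count / n
        smoothed = raw + alpha
        p_star[k] = smoothed / smoothed.sum()
    u_star = np.zeros_like(p_star)
    for k in range(k_dims):
        u = 1.0 / p_star[k]
        u_star[k] = u / u.sum()
    w = np.array([u_star[:, i].max() for i in range(n)])
    return p_star, u_star, w, w / w.sum()


@pytest.fixture(scope="session")
def mixture_95_5():
    """95/5 mixture of two well-separated Gaussians in latent space."""
    rng = np.random.default_rng(42)
    n_common, n_rare = 950, 50
    common = rng.normal(0.0, 1.0, size=(n_common, 3))
    rare = rng.normal(8.0, 1.0, size=(n_rare, 3))
    Z = np.vstack([common, rare])
    labels = np.array(["common"] * n_common + ["rare"] * n_rare)
    return Z, labels


@pytest.fixture(scope="session")
def two_group_counts():
    """Small 95/5 two-group NB count dataset with group labels."""
    names = ["common", "rare"]
    profiles = simulate.make_group_profiles(100, names, seed=3)
    profiles[0]["proportion"] = 0.95
    profiles[1]["proportion"] = 0.05
    spec = simulate.SyntheticSpec(n_genes=100, groups=profiles,
                                  n_cells=600, seed=3)
    return simulate.simulate_counts(spec)


@pytest.fixture()
def small_cellmatrix():
    rng = np.random.default_rng(0)
    return CellMatrix(
        X=rng.poisson(5.0, size=(30, 12)).astype(float),
        group=np.repeat(["a", "b", "c"], 10),
        condition=np.tile(["control", "perturbed"], 15),
    )
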