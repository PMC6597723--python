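import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.transform import Rotation

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_rigid_transform():
    """Factory of random proper rigid transforms (seeded)."""
    gen = np.random.default_rng(1234)

    def make():
        rot = Rotation.random(rng=gen).as_matrix()
        t = gen.uniform(-20.0, 20.0, size=3)
        return rot, t

    return make


@pytest.fixture(scope="session")
def rotation_grid_rmsd():
    """Brute-force superposition oracle: min RMSD over a Euler-angle grid.

    Independent of the SVD path: enumerates rotations at the given
    angular resolution, optimally translates (centroid match), and
    returns the smallest RMSD found.
    """

    def oracle(mobile, reference, step_deg: float = 5.0) -> float:
        mob = np.asarray(mobile, dtype=float)
        ref = np.asarray(reference, dtype=float)
        mob_c = mob - mob.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        step = np.deg2rad(step_deg)
        alphas = np.arange(0.0, 2 * np.pi, step)
        betas = np.arange(0.0, np.pi + step / 2, step)
        gammas = np.arange(0.0, 2 * np.pi, step)
        grid = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1)
        rots = Rotation.from_euler("zyz", grid.reshape(-1, 3)).as_matrix()
        moved = np.einsum("rij,nj->rni", rots, mob_c)
        rmsd = np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=2), axis=1))
        return float(rmsd.min())

    return oracle


@pytest.fixture(scope="session")
def kl_divergence():
    """KL(q ‖ p) over bins; empty q-bins contribute zero."""

    def kl(q, p):
        q = np.asarray(q, dtype=float)
        p = np.asarray(p, dtype=float)
        m = q > 0
        return float(np.sum(q[m] * np.log(q[m] / p[m])))

    return kl
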