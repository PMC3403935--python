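import numpy as np
import pytest

from rmsdprune import Ensemble, SyntheticSpec, make_ensemble


@pytest.fixture(scope="session")
def clustered_ensemble() -> tuple[Ensemble, np.ndarray]:
    """60 structures around 3 well-separated centers (tight noise)."""
    return make_ensemble(
        SyntheticSpec(n=60, k=3, n_residues=30, separation=6.0, sigma=0.3, seed=42)
    )


@pytest.fixture(scope="session")
def decoy_ensemble() -> Ensemble:
    """A decoy-like unimodal ensemble: one basin, broad conformational noise."""
    ens, _ = make_ensemble(
        SyntheticSpec(n=80, k=1, n_residues=30, separation=0.0, sigma=1.5, seed=7)
    )
    return ens


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent minimum-RMSD oracle: dense two-stage search over rotations.

    Centers both coordinate sets (the optimal translation for any fixed
    rotation aligns centroids) and scans Euler-angle grids, coarse then
    refined around the best cell.  Deliberately ignorant of the Kabsch
    solution it is used to check.
    """
    from scipy.spatial.transform import Rotation

    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def best_over(rots: Rotation) -> tuple[float, Rotation]:
        mats = rots.as_matrix()
        rotated = np.einsum("mij,nj->mni", mats, Q)
        msd = ((P[None] - rotated) ** 2).sum(axis=(1, 2)) / P.shape[0]
        k = int(np.argmin(msd))
        return float(np.sqrt(msd[k])), rots[k]

    coarse = np.deg2rad(10.0)
    a = np.arange(-np.pi, np.pi, coarse)
    b = np.arange(0, np.pi + 1e-9, coarse)
    grid = np.array(np.meshgrid(a, b, a, indexing="ij")).reshape(3, -1).T
    best, rot = best_over(Rotation.from_euler("zyz", grid))
    # Refine with shrinking rotation-vector grids composed onto the best
    # rotation so far (no Euler-angle gimbal trouble near the optimum).
    step = coarse
    for _ in range(6):
        offs = np.linspace(-step, step, 7)
        local = np.array(np.meshgrid(offs, offs, offs, indexing="ij")).reshape(3, -1).T
        cand, rot = best_over(Rotation.from_rotvec(local) * rot)
        best = min(best, cand)
        step /= 3.0
    return best
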