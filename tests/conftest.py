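import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def grid_mesh(nx: int, ny: int, z_fn=None, scale: float = 1.0) -> trimesh.Trimesh:
    """Regular triangulated grid over [0, scale]^2 with optional height z(x, y)."""
    xs = np.linspace(0, scale, nx)
    ys = np.linspace(0, scale, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    Z = z_fn(X, Y) if z_fn else np.zeros_like(X)
    v = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nx * ny).reshape(ny, nx)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    f = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def tube_mesh(radius: float, height: float, n_rings: int = 40, n_around: int = 80) -> trimesh.Trimesh:
    """Open cylinder barrel (no caps) with interior vertices away from the rims."""
    th = np.linspace(0, 2 * np.pi, n_around, endpoint=False)
    zs = np.linspace(0, height, n_rings)
    T, Z = np.meshgrid(th, zs)
    v = np.column_stack([radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()])
    idx = np.arange(n_rings * n_around).reshape(n_rings, n_around)
    f = []
    for i in range(n_rings - 1):
        for j in range(n_around):
            a, b = idx[i, j], idx[i, (j + 1) % n_around]
            c, d = idx[i + 1, j], idx[i + 1, (j + 1) % n_around]
            f += [[a, b, d], [a, d, c]]
    return trimesh.Trimesh(vertices=v, faces=np.array(f), process=False)


@pytest.fixture(scope="session")
def tooth_spec():
    from occlugen.synthetic_tooth import random_tooth_spec

    return random_tooth_spec(np.random.default_rng(42))


@pytest.fixture(scope="session")
def tooth_mesh(tooth_spec):
    from occlugen.synthetic_tooth import generate_tooth_mesh

    return generate_tooth_mesh(tooth_spec)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Four 64x64 triplets (3 train / 1 test) shared across GAN tests."""
    from occlugen.depth_projection import ProjectionConfig
    from occlugen.synthetic_tooth import generate_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(
        4, seed=11, outdir=outdir, config=ProjectionConfig(resolution=64)
    )
    return manifest
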