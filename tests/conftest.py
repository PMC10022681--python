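import numpy as np
import pytest

from chromotrace import LocusTrajectory, TrajectoryEnsemble


def make_trajectory(
    positions,
    dt=1.0,
    cell_id="c1",
    locus_id="L1",
    condition="",
    **metadata,
):
    positions = np.asarray(positions, dtype=float)
    return LocusTrajectory(
        cell_id=cell_id,
        locus_id=locus_id,
        condition=condition,
        times=np.arange(len(positions)) * dt,
        positions=positions,
        metadata=metadata,
    )


def rigid_motion(positions, angle, offset):
    """Apply rotation by ``angle`` about the origin then translation."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(positions) @ rot.T + np.asarray(offset)


@pytest.fixture
def simple_ensemble():
    return TrajectoryEnsemble(
        [
            make_trajectory([[0, 0], [1, 0], [2, 0]], cell_id="c1"),
            make_trajectory([[1, 1], [1, 2], [1, 3]], cell_id="c2"),
        ]
    )
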