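import numpy as np
import pytest

import holdscan as hs

#: literal 3-atom, 2-model PDB fixture used by the I/O tests
TINY_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00           C
HETATM    3  O   HOH W   1       7.500   8.250   9.125  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.100   2.100   3.100  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.100   5.100   6.100  1.00  0.00           C
HETATM    3  O   HOH W   1       7.600   8.350   9.225  1.00  0.00           O
ENDMDL
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


def make_topology(n, **overrides):
    """Minimal all-carbon protein topology for constructed-coordinate tests."""
    element = overrides.pop("element", np.array(["C"] * n, dtype="U2"))
    fields = dict(
        serial=np.arange(1, n + 1),
        name=np.array(["CA"] * n, dtype="U5"),
        resname=np.array(["ALA"] * n, dtype="U5"),
        chain=np.array(["A"] * n, dtype="U4"),
        resid=np.arange(1, n + 1),
        element=element,
        vdw_radius=np.array(
            [hs.traj.VDW_RADII.get(el, 1.70) for el in element]
        ),
        charge=np.zeros(n),
        is_water=np.zeros(n, dtype=bool),
        is_ligand=np.zeros(n, dtype=bool),
    )
    fields.update(overrides)
    return hs.Topology(**fields)


@pytest.fixture(scope="session")
def default_system():
    """The default synthetic system with ground truth (seed 7)."""
    spec = hs.SyntheticSpec(seed=7)
    traj, labels, schedule = hs.generate_system(spec)
    return spec, traj, labels, schedule


@pytest.fixture(scope="session")
def analyzed_system(default_system):
    """Default system taken through PCA -> FEL -> labeled basins."""
    spec, traj, labels, schedule = default_system
    model = hs.fit_pca(traj, "name CA")
    proj = hs.project(traj, model, k=2)
    fel = hs.build_fel(proj)
    basins = hs.find_minima(fel)
    assignment = hs.assign_frames(proj, fel, basins)
    hs.label_basins_temporal(basins, traj.times)
    frame_labels = np.array(
        [basins[i].label if i >= 0 else None for i in assignment], dtype=object
    )
    return dict(spec=spec, traj=traj, labels=labels, schedule=schedule,
                model=model, proj=proj, fel=fel, basins=basins,
                frame_labels=frame_labels)
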