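import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def pdb_line(
    serial: int,
    resname: str,
    chain: str,
    resnum: int,
    xyz,
    name: str = "CA",
    altloc: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    het: bool = False,
    element: str = "C",
) -> str:
    rec = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    name4 = name if len(name) >= 4 else f" {name:<3s}"  # PDB column convention
    return (
        f"{rec}{serial:5d} {name4}{altloc}{resname:<3s} {chain}{resnum:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}\n"
    )


def make_pdb(lines) -> str:
    return "".join(lines) + "END\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue chain with a water and a ligand to ignore."""
    text = make_pdb(
        [
            pdb_line(1, "ALA", "A", 1, (0.0, 0.0, 0.0)),
            pdb_line(2, "GLY", "A", 2, (3.0, 4.0, 0.0)),
            pdb_line(3, "SER", "A", 3, (6.0, 0.0, 0.0)),
            pdb_line(4, "HOH", "A", 101, (9.0, 9.0, 9.0), name="O", het=True, element="O"),
            pdb_line(5, "HEM", "A", 200, (1.0, 1.0, 1.0), name="FE", het=True, element="FE"),
        ]
    )
    path = tmp_path / "three.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
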