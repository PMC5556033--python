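import pytest

from pbflex import SyntheticScenario, distribution_for_neq

# hand-typed 5-residue chain: per-atom B-factors are the test oracle.
# Residue 3's CA carries two alternate locations (B has the higher occupancy).
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 11.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.421   0.000  1.00 12.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.100  1.00 21.00           N
ATOM      5  CA  GLY A   2       4.023   2.800   0.200  1.00 20.00           C
ATOM      6  C   GLY A   2       5.530   2.600   0.300  1.00 22.00           C
ATOM      7  N   SER A   3       6.231   3.721   0.200  1.00 31.00           N
ATOM      8  CA ASER A   3       7.712   3.701   0.300  0.40 99.00           C
ATOM      9  CA BSER A   3       7.702   3.711   0.310  0.60 30.00           C
ATOM     10  C   SER A   3       8.302   5.100   0.400  1.00 32.00           C
ATOM     11  N   VAL A   4       9.601   5.301   0.300  1.00 41.00           N
ATOM     12  CA  VAL A   4      10.402   6.502   0.400  1.00 40.00           C
ATOM     13  C   VAL A   4      11.903   6.200   0.500  1.00 42.00           C
ATOM     14  N   LEU A   5      12.704   7.301   0.400  1.00 51.00           N
ATOM     15  CA  LEU A   5      14.105   7.102   0.500  1.00 50.00           C
ATOM     16  C   LEU A   5      14.906   8.400   0.600  1.00 52.00           C
TER
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def toy_pdb_missing_ca(tmp_path):
    """Toy chain with residue 4's CA record removed."""
    lines = [l for l in TOY_PDB.splitlines() if not l.startswith("ATOM     12")]
    path = tmp_path / "toy_missing_ca.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def basic_scenario():
    """20 planted positions of Neq 2 (support 4), one distal variant edit.

    Position 12 swaps to a disjoint-leaning repertoire; position 5 is the
    nominal (untouched) mutation site, emulating a purely distal effect.
    """
    edit = distribution_for_neq(3.0, support=6, seed=999)
    return SyntheticScenario.from_neq_targets(
        [2.0] * 20,
        support=4,
        seed=11,
        run_plan_ns=(5, 5, 10),
        stride_ps=100.0,
        discard_ns=0.5,
        variant_edits={"VAR": {12: edit}},
    )
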