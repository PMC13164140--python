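"""Mechanism data model: builder, Arrhenius evaluation, conservation laws, I/O."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipoxkin import (
    ArrheniusParams,
    Mechanism,
    MechanismError,
    MechanismParseError,
    Reaction,
    SpeciesDef,
    conservation_laws,
    parse_mechanism,
    rate_constant,
    tomato_pomace_mechanism,
    write_mechanism,
)
from lipoxkin.mechanism import R_CAL


class TestBuiltinMechanism:
    def test_shape(self, mech):
        assert len(mech.species) == 11
        assert len(mech.reactions) == 6
        assert mech.stoich_matrix.shape == (11, 6)

    def test_initiation_parameters(self, mech):
        k = mech.reactions[0].kinetics
        assert k.A == 1.0e13 and k.Ea == 24_500.0 and k.n == 0.0

    def test_initial_fractions_sum_to_one(self, mech):
        x0 = mech.initial_mole_fractions
        assert x0.sum() == pytest.approx(1.0, abs=1e-12)
        assert x0[mech.species_index("N2")] == 0.779
        assert x0[mech.species_index("O2")] == 0.210
        assert x0[mech.species_index("LINOLEIC")] == 0.010
        assert x0[mech.species_index("LYCOPENE")] == 0.001

    def test_decomposition_stoichiometry_column(self, mech):
        j = next(
            i for i, rx in enumerate(mech.reactions) if rx.reactants == {"ROOH": 1}
        )
        col = mech.stoich_matrix[:, j]
        expected = np.zeros(11, dtype=int)
        expected[mech.species_index("ROOH")] = -1
        expected[mech.species_index("HEXANAL")] = 1
        expected[mech.species_index("FRAG12")] = 1
        assert (col == expected).all()

    def test_unimolecular_step_is_the_only_one(self, mech):
        molecularities = [rx.molecularity for rx in mech.reactions]
        assert molecularities.count(1) == 1
        assert set(molecularities) == {1, 2}


class TestRateConstant:
    def test_zero_activation_energy_gives_A(self):
        k = rate_constant(ArrheniusParams(1.0e12, 0.0, 0.0), 323.15)
        assert k == 1.0e12

    @pytest.mark.parametrize(
        "A,Ea,T",
        [(1.0e14, 14_000.0, 323.15), (1.0e14, 35_000.0, 363.15),
         (1.0e13, 24_500.0, 343.15), (1.0e11, 10_000.0, 363.15)],
    )
    def test_matches_direct_exponential_evaluation(self, A, Ea, T):
        # independent closed-form oracle
        assert rate_constant(ArrheniusParams(A, 0.0, Ea), T) == pytest.approx(
            A * math.exp(-Ea / (R_CAL * T)), rel=1e-12
        )

    def test_frozen_values(self):
        # frozen from the A*exp(-Ea/(R*T)) oracle
        assert rate_constant(ArrheniusParams(1.0e14, 0.0, 14_000.0), 323.15) == (
            pytest.approx(3.4028e4, rel=1e-4)
        )
        assert rate_constant(ArrheniusParams(1.0e14, 0.0, 35_000.0), 363.15) == (
            pytest.approx(8.6462e-8, rel=1e-4)
        )

    def test_temperature_exponent_supported(self):
        k = rate_constant(ArrheniusParams(2.0, 1.0, 0.0), 300.0)
        assert k == pytest.approx(600.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            rate_constant(ArrheniusParams(1.0, 0.0, 0.0), 0.0)
        with pytest.raises(ValueError):
            rate_constant(ArrheniusParams(1.0, 0.0, 0.0), -5.0)

    @given(
        Ea=st.floats(1.0, 50_000.0),
        T1=st.floats(250.0, 1000.0),
        dT=st.floats(1.0, 500.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_T_when_activated(self, Ea, T1, dT):
        kin = ArrheniusParams(1.0e10, 0.0, Ea)
        assert rate_constant(kin, T1 + dT) > rate_constant(kin, T1)


# ---------------------------------------------------------------------------
# Conservation laws


def rational_left_nullspace(S):
    """Independent oracle: rational Gaussian elimination on S^T (no sympy)."""
    S = [[Fraction(int(v)) for v in row] for row in np.asarray(S).T]  # rows = reactions
    n = len(S[0])
    # eliminate to find null space of the row space of S (w with S w = 0 ... careful):
    # we want w with w^T S_orig = 0  <=>  S_orig^T w = 0; S here IS S_orig^T.
    rows = [row[:] for row in S]
    pivots = {}
    r = 0
    for c in range(n):
        piv = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if piv is None:
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        rows[r] = [v / rows[r][c] for v in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots[c] = r
        r += 1
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        w = [Fraction(0)] * n
        w[fc] = Fraction(1)
        for c, pr in pivots.items():
            w[c] = -rows[pr][fc]
        basis.append(w)
    return basis


class TestConservationLaws:
    def test_every_basis_vector_annihilates_stoichiometry(self, mech):
        for w in conservation_laws(mech):
            assert (w @ mech.stoich_matrix == 0).all()
            assert w.dtype.kind == "i"

    def test_dimension_matches_rational_oracle(self, mech):
        # rank(S) is 5, not 6: propagation - ROO scavenging + LINRAD scavenging
        # cancels, so 11 species leave a 6-dimensional left null space
        oracle = rational_left_nullspace(mech.stoich_matrix)
        assert len(conservation_laws(mech)) == len(oracle) == 6

    @pytest.mark.parametrize(
        "members,weights",
        [
            (("N2",), (1,)),
            (("LYCOPENE", "LYCORAD"), (1, 1)),
            (("LINOLEIC", "LINRAD", "ROO", "ROOH", "HEXANAL"), (1, 1, 1, 1, 1)),
            (("HEXANAL", "FRAG12"), (1, -1)),
        ],
    )
    def test_expected_moiety_sums_are_conserved(self, mech, members, weights):
        w = np.zeros(len(mech.species), dtype=int)
        for name, wt in zip(members, weights):
            w[mech.species_index(name)] = wt
        # membership in the left null space == annihilates every reaction column
        assert (w @ mech.stoich_matrix == 0).all()


# ---------------------------------------------------------------------------
# Parsing


class TestMechanismIO:
    @pytest.mark.parametrize("dialect", ["native", "chemkin-subset"])
    def test_roundtrip_is_identity(self, mech, dialect):
        assert parse_mechanism(write_mechanism(mech, dialect), dialect) == mech

    def test_chemkin_unimolecular_line(self):
        text = (
            "SPECIES\nROOH\nHEXANAL\nFRAG12\nEND\n"
            "REACTIONS CAL/MOLE\nROOH=>HEXANAL+FRAG12 1.0E14 0.0 35000.\nEND\n"
        )
        m = parse_mechanism(text, "chemkin-subset")
        (rx,) = m.reactions
        assert rx.molecularity == 1
        assert rx.kinetics.A == 1.0e14 and rx.kinetics.Ea == 35_000.0

    def test_reversible_arrow_rejected_with_line_number(self):
        text = "SPECIES\nA\nB\nC\nEND\nREACTIONS\nA+B=C 1.0 0.0 0.0\nEND\n"
        with pytest.raises(MechanismParseError) as exc:
            parse_mechanism(text, "chemkin-subset")
        assert exc.value.line == 7

    def test_unknown_species_token_rejected(self):
        text = "SPECIES\nA\nEND\nREACTIONS\nA=>BOGUS 1.0 0.0 0.0\nEND\n"
        with pytest.raises(MechanismParseError, match="BOGUS"):
            parse_mechanism(text, "chemkin-subset")

    def test_malformed_rate_triple_rejected(self):
        text = "SPECIES\nA\nB\nEND\nREACTIONS\nA=>B 1.0 zero 0.0\nEND\n"
        with pytest.raises(MechanismParseError, match="rate triple"):
            parse_mechanism(text, "chemkin-subset")

    def test_duplicate_labels_rejected_in_native(self, mech):
        text = write_mechanism(mech, "native").replace(
            "label: oxygen addition", "label: initiation"
        )
        with pytest.raises(MechanismParseError, match="duplicate"):
            parse_mechanism(text, "native")

    def test_species_names_canonicalized_uppercase(self):
        assert SpeciesDef("linoleic", "substrate", 0.01).name == "LINOLEIC"
        rx = Reaction({"roo": 1, "linoleic": 1}, {"rooh": 1, "linrad": 1},
                      ArrheniusParams(1.0))
        assert set(rx.reactants) == {"ROO", "LINOLEIC"}


class TestInvariantEnforcement:
    def test_negative_A_rejected(self):
        with pytest.raises(MechanismError):
            ArrheniusParams(-1.0)

    def test_negative_Ea_rejected(self):
        with pytest.raises(MechanismError):
            ArrheniusParams(1.0, 0.0, -10.0)

    def test_termolecular_rejected(self):
        with pytest.raises(MechanismError, match="molecularity"):
            Reaction({"A": 2, "B": 1}, {"C": 1}, ArrheniusParams(1.0))

    def test_undeclared_species_in_reaction_rejected(self):
        with pytest.raises(MechanismError, match="undeclared"):
            Mechanism(
                species=[SpeciesDef("A", "substrate", 1.0)],
                reactions=[Reaction({"A": 1}, {"B": 1}, ArrheniusParams(1.0))],
            )

    def test_duplicate_species_rejected(self):
        with pytest.raises(MechanismError, match="duplicate"):
            Mechanism(
                species=[SpeciesDef("A"), SpeciesDef("a")], reactions=[]
            )
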