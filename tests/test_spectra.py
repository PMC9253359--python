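"""Peak assignment and % dimer quantification on synthetic spectra."""

import warnings

import numpy as np
import pytest

from curlikin import (
    ChargeEnvelope,
    MassSpectrum,
    PeakAssignment,
    SpeciesDefinition,
    assign_peaks,
    expected_mz,
    generate_mass_spectrum,
    percent_dimer,
)
from curlikin.errors import CurlikinError


class TestExpectedMz:
    def test_ten_kda_ten_plus(self):
        assert expected_mz(10000.0, 10) == pytest.approx(1001.00728)

    def test_singly_charged(self):
        assert expected_mz(10000.0, 1) == pytest.approx(10001.00728)

    @pytest.mark.parametrize("z", [0, -1, 2.5])
    def test_invalid_charge_rejected(self, z):
        with pytest.raises(ValueError):
            expected_mz(10000.0, z)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            expected_mz(0.0, 5)


class TestMassSpectrumInvariants:
    def test_decreasing_mz_rejected(self):
        with pytest.raises(ValueError):
            MassSpectrum(np.array([2.0, 1.0]), np.array([0.0, 0.0]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            MassSpectrum(np.array([1.0, 2.0]), np.array([0.0, -1.0]))


class TestAssignPeaks:
    def test_full_idp_envelope_assigned(self, monomer):
        """All 22 charge states of a disordered monomer (5+..26+) found."""
        env = {"monomer": ChargeEnvelope(5, 26, 12, 4.0)}
        spec = generate_mass_spectrum({"monomer": 1.0}, [monomer], env)
        asg = assign_peaks(spec, [monomer], env, tolerance=0.5)
        assert len(asg) == 22
        assert {a.charge for a in asg} == set(range(5, 27))
        for a in asg:
            assert abs(a.observed_mz - a.expected_mz) <= 0.5
            assert not a.ambiguous

    def test_displaced_peak_unassigned(self):
        # single Gaussian 1.5 Th away from where the species is expected
        mz = np.arange(990.0, 1010.0, 0.05)
        centre = expected_mz(10000.0, 10) + 1.5
        spec = MassSpectrum(mz, np.exp(-0.5 * ((mz - centre) / 0.3) ** 2))
        sp = SpeciesDefinition("p", 10000.0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = assign_peaks(spec, [sp], {"p": (10, 10)}, tolerance=0.5)
        assert asg == []

    def test_monomer_dimer_coincidence_flagged_ambiguous(self, monomer, dimer):
        # dimer at 2z has exactly the monomer's m/z at z
        env = {"monomer": (6, 6), "dimer": (12, 12)}
        spec = generate_mass_spectrum(
            {"monomer": 0.5, "dimer": 0.5},
            [monomer, dimer],
            {
                "monomer": ChargeEnvelope(6, 6, 6, 1.0),
                "dimer": ChargeEnvelope(12, 12, 12, 1.0),
            },
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = assign_peaks(spec, [monomer, dimer], env, tolerance=0.5)
        assert len(asg) == 1
        assert asg[0].ambiguous

    def test_empty_spectrum_rejected(self, monomer):
        with pytest.raises(CurlikinError):
            assign_peaks(
                MassSpectrum(np.array([]), np.array([])),
                [monomer],
                {"monomer": (5, 10)},
            )

    def test_assignment_deterministic(self, monomer, dimer, clean_envelopes):
        spec = generate_mass_spectrum(
            {"monomer": 0.8, "dimer": 0.2}, [monomer, dimer], clean_envelopes
        )
        a1 = assign_peaks(spec, [monomer, dimer], clean_envelopes)
        a2 = assign_peaks(spec, [monomer, dimer], clean_envelopes)
        assert a1 == a2


class TestPercentDimer:
    def test_equal_areas_give_fifty_percent(self):
        asg = [
            PeakAssignment("m", 10, 1000.0, 1000.0, 5.0),
            PeakAssignment("d", 15, 1500.0, 1500.0, 5.0),
        ]
        q = percent_dimer(asg, "m", "d")
        assert q.percent_dimer == pytest.approx(50.0)

    def test_no_dimer_gives_zero(self):
        asg = [PeakAssignment("m", 10, 1000.0, 1000.0, 5.0)]
        assert percent_dimer(asg, "m", "d").percent_dimer == 0.0

    def test_zero_total_area_rejected(self):
        with pytest.raises(CurlikinError):
            percent_dimer([], "m", "d")

    def test_ambiguous_assignments_excluded(self):
        asg = [
            PeakAssignment("m", 10, 1000.0, 1000.0, 5.0),
            PeakAssignment("d", 15, 1500.0, 1500.0, 5.0),
            PeakAssignment("d", 20, 1300.0, 1300.0, 100.0, ambiguous=True),
        ]
        assert percent_dimer(asg, "m", "d").percent_dimer == pytest.approx(50.0)

    def test_scale_invariance(self, monomer, dimer, clean_envelopes):
        spec = generate_mass_spectrum(
            {"monomer": 0.9, "dimer": 0.1}, [monomer, dimer], clean_envelopes
        )
        scaled = MassSpectrum(spec.mz, 37.5 * spec.intensity)
        q1 = percent_dimer(
            assign_peaks(spec, [monomer, dimer], clean_envelopes), "monomer", "dimer"
        )
        q2 = percent_dimer(
            assign_peaks(scaled, [monomer, dimer], clean_envelopes), "monomer", "dimer"
        )
        assert q1.percent_dimer == pytest.approx(q2.percent_dimer, rel=1e-9)

    @pytest.mark.parametrize("fraction", [0.025, 0.05, 0.10, 0.125, 0.3])
    def test_noiseless_share_recovery(self, monomer, dimer, clean_envelopes, fraction):
        """With equal response and clean envelopes, % dimer ~ mole fraction."""
        spec = generate_mass_spectrum(
            {"monomer": 1.0 - fraction, "dimer": fraction},
            [monomer, dimer],
            clean_envelopes,
        )
        q = percent_dimer(
            assign_peaks(spec, [monomer, dimer], clean_envelopes), "monomer", "dimer"
        )
        assert abs(q.percent_dimer - 100.0 * fraction) < 0.5


class TestGenerateMassSpectrum:
    def test_single_species_single_charge_peak_position(self):
        sp = SpeciesDefinition("p", 10000.0, 1)
        env = {"p": ChargeEnvelope(10, 10, 10, 1.0)}
        spec = generate_mass_spectrum(
            {"p": 1.0}, [sp], env, peak_width=1.0, mz_range=(900, 1100), mz_step=0.01
        )
        apex = spec.mz[np.argmax(spec.intensity)]
        assert apex == pytest.approx(1001.00728, abs=0.01)

    def test_area_linear_in_mole_fraction(self, monomer, dimer, clean_envelopes):
        spec = generate_mass_spectrum(
            {"monomer": 0.8, "dimer": 0.2}, [monomer, dimer], clean_envelopes
        )
        asg = assign_peaks(spec, [monomer, dimer], clean_envelopes)
        mono = sum(a.area for a in asg if a.species == "monomer")
        dim = sum(a.area for a in asg if a.species == "dimer")
        assert mono / dim == pytest.approx(4.0, rel=0.01)

    def test_total_area_conserved(self, monomer, dimer, clean_envelopes):
        # noiseless total integral = sum of fraction x response
        spec = generate_mass_spectrum(
            {"monomer": 0.6, "dimer": 0.4},
            [monomer, dimer],
            clean_envelopes,
            response={"monomer": 2.0},
        )
        total = np.trapezoid(spec.intensity, spec.mz)
        # monomer response 2.0; dimer = mean of its components' = 2.0
        assert total == pytest.approx(0.6 * 2.0 + 0.4 * 2.0, rel=1e-6)

    def test_empty_abundances_rejected(self, monomer, clean_envelopes):
        with pytest.raises(ValueError):
            generate_mass_spectrum({}, [monomer], clean_envelopes)
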