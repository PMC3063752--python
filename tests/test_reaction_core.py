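"""Unit and property tests for the molecule-level reaction rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replisim.reaction_core import (Bond, ConfigurationError, Form,
                                    InvalidEventError, KineticParams,
                                    ReplicatorState, Role,
                                    complex_dissociation_rate,
                                    complex_formation_rate, form_complex,
                                    mutate_offspring, replicate)


def mol(role=Role.Rp, form=Form.RNA, rrec=0.4, drec=0.0, **kw):
    return ReplicatorState(role=role, form=form, rrec=rrec, drec=drec, **kw)


class TestComplexFormation:
    @pytest.mark.parametrize("catalyst, template, expected", [
        # idealized self-replicator binding a plain RNA template
        (dict(rrec=0.4, drec=0.0), dict(role=Role.Rp, form=Form.RNA), 0.4),
        # zero recognition -> no complex formation
        (dict(rrec=0.0, drec=1.0), dict(role=Role.Rp, form=Form.RNA), 0.0),
        # DNA template read through the DNA-recognition constant
        (dict(rrec=0.0, drec=1.0), dict(role=Role.Dp, form=Form.DNA), 1.0),
    ])
    def test_matching_recognition_constant(self, catalyst, template,
                                           expected):
        cat = mol(**catalyst)
        tmpl = mol(**template, rrec=0.3, drec=0.3)
        assert complex_formation_rate(cat, tmpl, KineticParams()) == expected

    def test_parasite_template_gets_advantage_factor(self):
        cat = mol(rrec=0.5)
        par = mol(role=Role.parasite, form=Form.RNA)
        rate = complex_formation_rate(cat, par, KineticParams(k_p=2.0))
        assert rate == pytest.approx(1.0)
        # the factor applies to DNA-form parasites too
        par_dna = mol(role=Role.parasite, form=Form.DNA)
        cat2 = mol(rrec=0.0, drec=0.5)
        assert complex_formation_rate(
            cat2, par_dna, KineticParams(k_p=2.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [
        dict(role=Role.parasite, form=Form.RNA),
        dict(role=Role.Rp, form=Form.DNA),
    ])
    def test_noncatalytic_molecules_cannot_be_catalysts(self, bad):
        with pytest.raises(InvalidEventError):
            complex_formation_rate(mol(**bad), mol(), KineticParams())

    @pytest.mark.parametrize("rrec, expected", [(0.4, 0.6), (0.0, 1.0)])
    def test_dissociation_is_complement(self, rrec, expected):
        assert complex_dissociation_rate(
            Form.RNA, mol(rrec=rrec)) == pytest.approx(expected)

    def test_full_recognition_means_no_dissociation(self):
        assert complex_dissociation_rate(Form.DNA, mol(drec=1.0)) == 0.0


class TestMutation:
    def test_no_mutation_is_identity(self, rng):
        out = mutate_offspring(Role.Rp, 0.37, 0.81, KineticParams(), rng)
        assert out == (Role.Rp, 0.37, 0.81)

    def test_step_clamped_at_upper_bound(self, rng):
        params = KineticParams(mu_r=1.0, delta=0.2)
        for _ in range(200):
            _, rr, _ = mutate_offspring(Role.Rp, 0.95, 0.0, params, rng)
            assert 0.0 <= rr <= 1.0

    def test_channel_frequencies_and_exclusivity(self, rng):
        """Channel rates match the configured probabilities (binomial
        oracle), and no offspring shows two mutations at once."""
        params = KineticParams(mu_r=0.01, mu_d=0.02, mu_rp_to_dp=0.005,
                               mu_par=0.005, delta=0.05)
        n = 100_000
        changed = {"rrec": 0, "drec": 0, "role": 0, "par": 0, "multi": 0}
        for _ in range(n):
            role, rr, dd = mutate_offspring(Role.Rp, 0.5, 0.5, params, rng)
            hits = sum([rr != 0.5, dd != 0.5,
                        role in (Role.Dp, Role.parasite)])
            if hits > 1:
                changed["multi"] += 1
            changed["rrec"] += rr != 0.5
            changed["drec"] += dd != 0.5
            changed["role"] += role == Role.Dp
            changed["par"] += role == Role.parasite
        assert changed["multi"] == 0
        for key, p in [("rrec", 0.01), ("drec", 0.02), ("role", 0.005),
                       ("par", 0.005)]:
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(changed[key] - n * p) < 3 * sigma, key

    def test_parasites_breed_true(self, rng):
        params = KineticParams(mu_r=0.5, mu_d=0.5)
        out = mutate_offspring(Role.parasite, 0.5, 0.5, params, rng)
        assert out == (Role.parasite, 0.5, 0.5)

    def test_channel_sum_validated_at_construction(self):
        with pytest.raises(ConfigurationError):
            KineticParams(mu_r=0.7, mu_d=0.6)

    @given(rrec=st.floats(0, 1), drec=st.floats(0, 1),
           seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_recognition_never_leaves_unit_interval(self, rrec, drec, seed):
        r = np.random.default_rng(seed)
        params = KineticParams(mu_r=0.45, mu_d=0.45, delta=0.3)
        role, rr, dd = Role.Rp, rrec, drec
        for _ in range(20):
            role, rr, dd = mutate_offspring(role, rr, dd, params, r)
            assert 0.0 <= rr <= 1.0 and 0.0 <= dd <= 1.0


class TestReplicate:
    def test_product_form_follows_catalyst_role(self, rng):
        params = KineticParams()
        # transcription: Rp catalyst reads a DNA-form Dp gene -> RNA product
        cat = mol(role=Role.Rp, rrec=0.0, drec=1.0)
        tmpl = mol(role=Role.Dp, form=Form.DNA, rrec=0.0, drec=1.0)
        form_complex(cat, tmpl)
        product = replicate(cat, tmpl, params, rng)
        assert (product.role, product.form) == (Role.Dp, Form.RNA)
        # reverse transcription: Dp catalyst reads RNA-form Rp -> DNA product
        cat2 = mol(role=Role.Dp, rrec=1.0, drec=0.0)
        tmpl2 = mol(role=Role.Rp, form=Form.RNA)
        form_complex(cat2, tmpl2)
        product2 = replicate(cat2, tmpl2, params, rng)
        assert (product2.role, product2.form) == (Role.Rp, Form.DNA)

    def test_mutation_free_copy_and_complex_dissolution(self, rng):
        cat = mol(rrec=0.8)
        tmpl = mol(rrec=0.31, drec=0.07)
        form_complex(cat, tmpl)
        product = replicate(cat, tmpl, KineticParams(), rng)
        assert (product.rrec, product.drec) == (0.31, 0.07)
        assert cat.bond == Bond.free and tmpl.bond == Bond.free
        assert cat.partner is None and tmpl.partner is None
        assert product.bond == Bond.free

    def test_lineage_label_is_template_side(self, rng):
        from replisim.reaction_core import Label

        cat = mol(role=Role.Dp, rrec=1.0)
        tmpl = mol(role=Role.Rp, form=Form.RNA,
                   lineage_label=Label.RNA_origin)
        form_complex(cat, tmpl)
        product = replicate(cat, tmpl, KineticParams(), rng)
        # product is DNA-form, yet carries the template's RNA-origin label
        assert product.form == Form.DNA
        assert product.lineage_label == Label.RNA_origin


class TestStateInvariants:
    def test_dna_form_never_on_catalyst_side(self):
        bad = mol(form=Form.DNA)
        bad.bond = Bond.catalyst_in_complex
        bad.partner = mol()
        bad.partner.partner = bad
        bad.partner.bond = Bond.template_in_complex
        with pytest.raises(ValueError):
            bad.validate()

    def test_partner_backreference_checked(self):
        a, b = mol(), mol()
        a.bond = Bond.catalyst_in_complex
        a.partner = b
        with pytest.raises(ValueError):
            a.validate()

    def test_kinetic_params_validation(self):
        with pytest.raises(ConfigurationError):
            KineticParams(k=0)
        with pytest.raises(ConfigurationError):
            KineticParams(k_p=0.5)
        with pytest.raises(ConfigurationError):
            KineticParams(d_rna=-0.1)
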