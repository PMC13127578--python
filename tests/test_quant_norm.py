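"""Normalization factors, aggregation arithmetic and ambiguity resolution."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qxlms.quant_norm import (
    AmbiguityError,
    NormalizationError,
    aggregate_links,
    build_evidence_counts,
    compute_norm_factors,
    norm_factor_map,
    resolve_ambiguities,
    resolve_ambiguous_site,
)
from qxlms.xlink_io import PeptideQuant, ResidueRef


def carrier(intensities):
    return PeptideQuant(
        peptide_sequence="AAAAAA", charge=2, link_kind="unmodified",
        assigned_sites=(), intensities=dict(intensities),
    )


def linked(site_index, intensities, kind="monolink", charge=2, sites=None,
           candidates=()):
    if sites is None:
        sites = (ResidueRef("P1", site_index, "K"),)
    return PeptideQuant(
        peptide_sequence=f"PEP{site_index}C{charge}", charge=charge,
        link_kind=kind, assigned_sites=sites, intensities=dict(intensities),
        ambiguous_candidates=tuple(candidates),
    )


def cells(*values, condition="control"):
    return {(condition, str(i + 1)): v for i, v in enumerate(values)}


class TestNormFactors:
    def test_totals_100_200_400_give_factors_half_one_two(self):
        # geometric mean of (100, 200, 400) is exactly 200
        profiles = compute_norm_factors([carrier(cells(100.0, 200.0, 400.0))])
        assert [p.norm_factor for p in profiles] == pytest.approx([0.5, 1.0, 2.0], rel=1e-12)
        assert [p.total_unreacted_signal for p in profiles] == [100, 200, 400]

    def test_equal_totals_give_unit_factors(self):
        profiles = compute_norm_factors([carrier(cells(300.0, 300.0, 300.0))])
        assert [p.norm_factor for p in profiles] == pytest.approx([1, 1, 1])

    def test_replicate_without_unreacted_signal_errors(self):
        peptides = [
            carrier(cells(100.0, 100.0)),
            linked(5, cells(10.0, 10.0, 10.0)),
        ]
        with pytest.raises(NormalizationError, match="control/3"):
            compute_norm_factors(peptides)

    @pytest.mark.parametrize("scale", [0.25, 2.0, 10.0])
    def test_scaling_one_replicate_is_cancelled_up_to_the_anchor(self, scale):
        """Multiplying every intensity of one replicate by c leaves the
        normalized profile unchanged up to the shared geometric-mean anchor
        (which shifts by c**(1/R)); all intensity ratios between replicates
        are exactly invariant, so downstream fold changes are too."""
        base_carrier = cells(100.0, 150.0, 200.0)
        base_link = cells(10.0, 20.0, 30.0)

        def normalized(carrier_cells, link_cells):
            peptides = [carrier(carrier_cells), linked(5, link_cells)]
            aggregated = aggregate_links(peptides, compute_norm_factors(peptides))
            return aggregated[0].normalized_intensity

        reference = normalized(base_carrier, base_link)
        scaled_carrier = dict(base_carrier)
        scaled_link = dict(base_link)
        scaled_carrier[("control", "2")] *= scale
        scaled_link[("control", "2")] *= scale
        perturbed = normalized(scaled_carrier, scaled_link)
        anchor_shift = scale ** (1.0 / 3.0)
        for pair in reference:
            assert perturbed[pair] == pytest.approx(
                reference[pair] * anchor_shift, rel=1e-12
            )


class TestAggregation:
    def test_charge_states_sum(self):
        peptides = [
            carrier(cells(100.0)),
            linked(5, cells(100.0), charge=2),
            linked(5, cells(50.0), charge=3),
        ]
        aggregated = aggregate_links(peptides, compute_norm_factors(peptides))
        assert len(aggregated) == 1
        assert aggregated[0].normalized_intensity[("control", "1")] == pytest.approx(150.0, rel=1e-12)
        assert aggregated[0].n_member_peptides == 2

    def test_single_member_is_identity(self):
        peptides = [carrier(cells(100.0, 100.0)), linked(5, cells(7.0, 9.0))]
        aggregated = aggregate_links(peptides, compute_norm_factors(peptides))
        got = aggregated[0].normalized_intensity
        assert got[("control", "1")] == pytest.approx(7.0, rel=1e-12)
        assert got[("control", "2")] == pytest.approx(9.0, rel=1e-12)

    def test_different_length_peptides_same_monolinked_residue_combine(self):
        short = linked(5, cells(10.0))
        long = PeptideQuant(
            peptide_sequence="LONGERPEPTIDE", charge=2, link_kind="monolink",
            assigned_sites=(ResidueRef("P1", 5, "K"),), intensities=cells(30.0),
        )
        peptides = [carrier(cells(100.0)), short, long]
        aggregated = aggregate_links(peptides, compute_norm_factors(peptides))
        assert len(aggregated) == 1
        assert aggregated[0].normalized_intensity[("control", "1")] == pytest.approx(40.0, rel=1e-12)

    def test_cell_missing_only_if_missing_in_all_members(self):
        a = linked(5, {("control", "1"): 10.0, ("control", "2"): None})
        b = linked(5, {("control", "1"): None, ("control", "2"): None}, charge=3)
        peptides = [carrier(cells(100.0, 100.0)), a, b]
        aggregated = aggregate_links(peptides, compute_norm_factors(peptides))
        cells_out = aggregated[0].normalized_intensity
        assert cells_out[("control", "1")] == pytest.approx(10.0, rel=1e-12)
        assert cells_out[("control", "2")] is None

    def test_unresolved_ambiguity_refused(self):
        ambiguous = linked(
            5, cells(10.0), candidates=(ResidueRef("P1", 5, "K"),
                                        ResidueRef("P1", 9, "S")),
        )
        peptides = [carrier(cells(100.0)), ambiguous]
        with pytest.raises(AmbiguityError, match="resolve_ambiguities"):
            aggregate_links(peptides, compute_norm_factors(peptides))

    def test_conservation_and_order_invariance(self):
        rng = random.Random(7)
        peptides = [carrier(cells(120.0, 80.0, 100.0))]
        for i in range(30):
            peptides.append(
                linked(
                    5 * (i % 6 + 1),
                    cells(*(rng.uniform(1, 100) for _ in range(3))),
                    charge=2 + i % 3,
                )
            )
        profiles = compute_norm_factors(peptides)
        factors = norm_factor_map(profiles)
        aggregated = aggregate_links(peptides, profiles)

        for pair in cells(0, 0, 0):
            total_in = sum(
                p.intensities[pair] / factors[pair]
                for p in peptides
                if not p.is_unmodified
            )
            total_out = sum(a.normalized_intensity[pair] for a in aggregated)
            assert total_out == pytest.approx(total_in, rel=1e-12)

        shuffled = peptides[:]
        rng.shuffle(shuffled)
        again = aggregate_links(shuffled, profiles)
        assert [a.link.key for a in again] == [a.link.key for a in aggregated]
        for x, y in zip(again, aggregated):
            for pair, value in y.normalized_intensity.items():
                assert x.normalized_intensity[pair] == pytest.approx(
                    value, rel=1e-12
                )


class TestAmbiguity:
    def ref(self, index, code="K"):
        return ResidueRef("P1", index, code)

    def test_lysine_preferred_over_serine(self):
        pep = linked(206, cells(1.0),
                     candidates=(self.ref(206), self.ref(210, "S")))
        assert resolve_ambiguous_site(pep) == self.ref(206)

    def test_most_evidence_wins_among_lysines(self):
        pep = linked(206, cells(1.0),
                     candidates=(self.ref(206), self.ref(207)))
        counts = {("P1", 206): 5, ("P1", 207): 2}
        assert resolve_ambiguous_site(pep, counts) == self.ref(206)
        counts = {("P1", 206): 1, ("P1", 207): 4}
        assert resolve_ambiguous_site(pep, counts) == self.ref(207)

    def test_tie_breaks_to_lowest_index(self):
        pep = linked(207, cells(1.0),
                     candidates=(self.ref(207), self.ref(206)))
        counts = {("P1", 206): 3, ("P1", 207): 3}
        assert resolve_ambiguous_site(pep, counts) == self.ref(206)

    def test_no_reactive_candidate_errors(self):
        pep = linked(10, cells(1.0),
                     candidates=(self.ref(10, "E"), self.ref(12, "G")))
        with pytest.raises(AmbiguityError):
            resolve_ambiguous_site(pep)

    def test_evidence_counts_count_species_not_peptides(self):
        # the same link species seen at two charge states is one observation
        peptides = [
            linked(5, cells(1.0), charge=2),
            linked(5, cells(1.0), charge=3),
            linked(5, cells(1.0), kind="interpeptide",
                   sites=(self.ref(5), ResidueRef("P2", 9, "K"))),
        ]
        counts = build_evidence_counts(peptides)
        assert counts[("P1", 5)] == 2  # one monolink species + one cross-link

    def test_resolve_ambiguities_rewrites_site(self):
        ambiguous = linked(
            206, cells(1.0),
            candidates=(self.ref(206), self.ref(210, "S")),
        )
        resolved = resolve_ambiguities([ambiguous])
        assert resolved[0].assigned_sites == (self.ref(206),)
        assert not resolved[0].is_ambiguous


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    totals=st.lists(
        st.floats(min_value=1.0, max_value=1e6, allow_nan=False),
        min_size=2, max_size=6,
    )
)
def test_norm_factors_have_unit_geometric_mean(totals):
    """The factors' geometric mean is 1 regardless of the totals."""
    import numpy as np

    profiles = compute_norm_factors(
        [carrier({("c", str(i)): t for i, t in enumerate(totals)})]
    )
    log_mean = np.mean([np.log(p.norm_factor) for p in profiles])
    assert abs(log_mean) < 1e-9
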