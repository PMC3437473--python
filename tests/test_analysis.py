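"""Community analyses: similarity, positional immunity, strain summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crisprcoevo.analysis import (
    morisita_horn,
    proportion_table,
    relative_immunity_profile,
    saturation_time,
    similarity_matrix,
    strain_summaries,
)
from crisprcoevo.simulator import SimulationRecord, Snapshot


class TestMorisitaHorn:
    def test_hand_worked_example(self):
        assert morisita_horn({"A": 3, "B": 1}, {"A": 1, "B": 3}) == pytest.approx(0.6)

    def test_self_similarity_is_one(self):
        c = {"A": 5.0, "B": 2.5, "C": 0.1}
        assert morisita_horn(c, c) == pytest.approx(1.0)

    def test_disjoint_communities_have_zero_similarity(self):
        assert morisita_horn({"A": 3, "B": 1}, {"C": 2, "D": 9}) == 0.0

    def test_empty_community_is_an_error(self):
        with pytest.raises(ValueError):
            morisita_horn({}, {"A": 1})

    @given(
        scale1=st.floats(1e-3, 1e6), scale2=st.floats(1e-3, 1e6),
        a=st.floats(0.1, 100), b=st.floats(0.1, 100), c=st.floats(0.1, 100),
    )
    def test_invariant_under_density_rescaling(self, scale1, scale2, a, b, c):
        c1 = {"A": a, "B": b}
        c2 = {"B": b, "C": c}
        base = morisita_horn(c1, c2)
        scaled = morisita_horn(
            {k: v * scale1 for k, v in c1.items()},
            {k: v * scale2 for k, v in c2.items()},
        )
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 1.0 + 1e-12


class TestSimilarityMatrix:
    def test_unit_diagonal_and_symmetry(self, short_default_record):
        mat = similarity_matrix(short_default_record, kind="host", interval=10.0)
        vals = mat.values
        assert np.allclose(np.diag(vals), 1.0)
        assert np.allclose(vals, vals.T)
        assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()

    def test_interval_subsamples_grid(self, short_default_record):
        full = similarity_matrix(short_default_record, kind="virus")
        sub = similarity_matrix(short_default_record, kind="virus", interval=20.0)
        assert len(sub) < len(full)
        assert np.all(np.diff(sub.index.values) >= 20.0 * (1 - 1e-9))


def _toy_record(host_loci, viral_genomes, V, u_max=8, times=(0.0,)):
    """Minimal hand-built record: constant community at each time."""
    genealogy = {}
    host_ids = tuple(range(1, len(host_loci) + 1))
    virus_ids = tuple(range(101, 101 + len(viral_genomes)))
    for sid, locus in zip(host_ids, host_loci):
        genealogy[sid] = {
            "kind": "host", "alleles": list(locus), "parent_id": None,
            "birth_time": 0.0, "death_time": None,
        }
    for sid, genome in zip(virus_ids, viral_genomes):
        genealogy[sid] = {
            "kind": "virus", "alleles": list(genome), "parent_id": None,
            "birth_time": 0.0, "death_time": None,
        }
    snaps = [
        Snapshot(
            t=t, host_ids=host_ids, host_densities=np.ones(len(host_ids)),
            virus_ids=virus_ids, virus_densities=np.asarray(V, dtype=float),
        )
        for t in times
    ]
    return SimulationRecord(
        snapshots=snaps, genealogy=genealogy, events=[], termination="t_max",
        t_end=times[-1], config=None,
    )


class TestRelativeImmunity:
    def test_leading_spacer_match_gives_flat_unit_profile(self):
        locus = tuple(range(1, 9))  # allele 1 leads
        genome = (1, 20, 21, 22, 23, 24, 25, 26, 27, 28)
        rec = _toy_record([locus], [genome], V=[1e5])
        profile = relative_immunity_profile(rec, u_max=8)
        assert np.allclose(profile.values, 1.0)

    def test_depth_resolved_profile_on_constructed_community(self):
        # virus A matched at locus position 1, virus B only at position 4
        host = (1, 30, 31, 2, 32, 33, 34, 35)
        vA = (1,) + tuple(range(50, 59))
        vB = (2,) + tuple(range(60, 69))
        rec = _toy_record([host], [vA, vB], V=[3e5, 1e5])
        profile = relative_immunity_profile(rec, u_max=8)
        # immunity(n<4) = 0.75, immunity(n>=4) = 1.0
        assert np.allclose(profile.values[:3], 0.75)
        assert np.allclose(profile.values[3:], 1.0)

    def test_profile_monotone_with_unit_endpoint(self, short_default_record, default_ensemble):
        rec = default_ensemble[0]
        profile = relative_immunity_profile(rec)
        assert profile.iloc[-1] == pytest.approx(1.0)
        assert (np.diff(profile.values) >= -1e-12).all()

    def test_unsaturated_record_raises(self):
        rec = _toy_record([(1, 2)], [(1,) + tuple(range(40, 49))], V=[1e5])
        with pytest.raises(ValueError):
            saturation_time(rec, u_max=8)


class TestStrainSummaries:
    def test_mutation_free_run_counts_and_censoring(self, lv_pair_record):
        record, _ = lv_pair_record
        tables = strain_summaries(record)
        counts = tables["counts"]
        assert (counts["n_host_strains"] == 1).all()
        assert (counts["n_virus_strains"] == 1).all()
        lifetimes = tables["lifetimes"]
        assert lifetimes["censored"].all()
        assert np.allclose(lifetimes["lifetime"], record.t_end)

    def test_counts_match_genealogy_reconstruction(self, short_default_record):
        rec = short_default_record
        gen = rec.genealogy
        for snap in rec.snapshots:
            for kind, ids in (("host", snap.host_ids), ("virus", snap.virus_ids)):
                live = sum(
                    1
                    for e in gen.values()
                    if e["kind"] == kind
                    and e["birth_time"] <= snap.t
                    and (e["death_time"] is None or e["death_time"] > snap.t)
                )
                assert live == len(ids)

    def test_proportion_filter_arithmetic(self, short_default_record):
        table = proportion_table(short_default_record, kind="virus", min_fraction=0.01)
        assert (table["proportion"] >= 0.01).all()
        for t, grp in table.groupby("time"):
            assert grp["proportion"].sum() <= 1.0 + 1e-9
            assert grp["strain_id"].is_unique
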