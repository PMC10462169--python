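"""Screening cascade: affinity thresholds, Lipinski, property ranges, ranking."""

import numpy as np
import pandas as pd
import pytest

from sgnc.codec import MoleculeRecord
from sgnc.exceptions import DataError, DomainError
from sgnc.screening import (
    PROPERTY_NAMES,
    PropertyProfile,
    RangeTable,
    ScreenVerdict,
    affinity_filter,
    classify_properties,
    lipinski_filter,
    novelty_filter,
    rank_leads,
)
from sgnc.similarity import cosine_similarity


def _panel(rows):
    return pd.DataFrame(rows, columns=["DAT", "NET", "SERT", "hERG"])


def _profile(mol_id="p", **overrides):
    base = dict(
        caco2=-4.8, f20=0.1, pgp_sub=0.1, pgp_inh=0.1, vd=1.0,
        t_half=0.1, fdamdd=0.1, sas=3.0, logp=1.5, logs=-2.0,
    )
    base.update(overrides)
    return PropertyProfile(id=mol_id, **base)


class TestAffinityFilter:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((-10, -10, -10, -7), True),
            ((-10, -10, -10, -9), False),  # hERG bound too tightly
            ((-9.54, -10, -10, -7), False),  # boundary: strict inequality
            ((-10, -9.0, -10, -7), False),  # one transporter too weak
            ((-10, -10, -10, -8.18), False),  # hERG boundary is strict too
        ],
    )
    def test_printed_thresholds(self, row, expected):
        assert affinity_filter(_panel([row])).tolist() == [expected]

    def test_missing_column_rejected(self):
        with pytest.raises(DataError):
            affinity_filter(pd.DataFrame({"DAT": [-10.0], "NET": [-10.0], "SERT": [-10.0]}))


class TestLipinskiFilter:
    def _mol(self, mw, logp, nhd, nha):
        return MoleculeRecord(
            smiles="C", id="x",
            descriptors={"mw": mw, "logp": logp, "nhd": nhd, "nha": nha},
        )

    def test_catalogued_reference_descriptors_pass(self):
        ok, flags = lipinski_filter(self._mol(300.140, 4.464, 0, 2))
        assert ok and all(flags.values())

    def test_boundaries_inclusive(self):
        ok, _ = lipinski_filter(self._mol(500.0, 5.0, 5, 10))
        assert ok

    @pytest.mark.parametrize(
        "mw,logp,nhd,nha,bad",
        [
            (500.01, 1.0, 0, 0, "mw"),
            (300, 5.2, 0, 0, "logp"),
            (300, 1.0, 6, 0, "nhd"),
            (300, 1.0, 0, 11, "nha"),
        ],
    )
    def test_single_criterion_violation_fails(self, mw, logp, nhd, nha, bad):
        ok, flags = lipinski_filter(self._mol(mw, logp, nhd, nha))
        assert not ok
        assert not flags[bad]
        assert all(v for k, v in flags.items() if k != bad)

    def test_missing_descriptor_rejected(self):
        with pytest.raises(DataError):
            lipinski_filter(MoleculeRecord(smiles="C", id="x", descriptors={"mw": 100.0}))


class TestClassifyProperties:
    def test_all_excellent_profile(self):
        v = classify_properties(_profile())
        assert v.overall_pass
        assert v.pct_excellent == 100.0
        assert set(v.classes.values()) == {"excellent"}

    def test_score_in_medium_band(self):
        v = classify_properties(_profile(f20=0.5))
        assert v.classes["f20"] == "medium"
        assert v.overall_pass
        assert v.pct_excellent == 90.0

    def test_shared_boundary_point_is_excellent(self):
        # 0.3 belongs to the closed excellent interval, not the medium band
        v = classify_properties(_profile(f20=0.3))
        assert v.classes["f20"] == "excellent"

    def test_sas_above_six_fails_outright(self):
        v = classify_properties(_profile(sas=7.0))
        assert v.classes["sas"] == "fail"
        assert not v.overall_pass

    def test_no_medium_band_means_fail_outside_excellent(self):
        v = classify_properties(_profile(logp=3.5))
        assert v.classes["logp"] == "fail"

    @pytest.mark.parametrize(
        "prop,fail_val,med_val,exc_val",
        [
            ("f20", 0.9, 0.5, 0.2),
            ("pgp_inh", 0.8, 0.65, 0.0),
            ("t_half", 0.99, 0.31, 0.3),
        ],
    )
    def test_monotone_in_each_scored_property(self, prop, fail_val, med_val, exc_val):
        order = {"fail": 0, "medium": 1, "excellent": 2}
        classes = [
            classify_properties(_profile(**{prop: v})).classes[prop]
            for v in (fail_val, med_val, exc_val)
        ]
        assert order[classes[0]] <= order[classes[1]] <= order[classes[2]]

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            _profile(fdamdd=1.2)

    def test_custom_range_table(self):
        from sgnc.screening import Interval, default_range_table

        ranges = default_range_table()
        ranges["sas"] = (Interval(-np.inf, 4.0, lo_closed=False, hi_closed=False), None)
        v = classify_properties(_profile(sas=5.0), RangeTable(ranges))
        assert v.classes["sas"] == "fail"


class TestNoveltyFilter:
    def test_candidate_equal_to_reference_fails(self, rng):
        z = rng.normal(size=6)
        mol = MoleculeRecord(smiles="C", id="x")
        assert novelty_filter([(mol, z)], [z.copy()]) == [False]

    def test_orthogonal_candidate_passes(self):
        mol = MoleculeRecord(smiles="C", id="x")
        assert novelty_filter([(mol, np.array([1.0, 0, 0]))], [np.array([0.0, 1, 0])]) == [True]

    def test_matches_brute_force_max_over_refs(self, rng):
        refs = [rng.normal(size=5) for _ in range(3)]
        cands = [
            (MoleculeRecord(smiles="C" * (i + 1), id=f"c{i}"), rng.normal(size=5))
            for i in range(50)
        ]
        got = novelty_filter(cands, refs, max_sim=0.5)
        brute = [
            max(cosine_similarity(z, r) for r in refs) < 0.5 for _, z in cands
        ]
        assert got == brute


class TestRankLeads:
    def _verdict(self, mol_id, pct, overall=True):
        classes = {k: "excellent" for k in PROPERTY_NAMES}
        return ScreenVerdict(id=mol_id, classes=classes, overall_pass=overall, pct_excellent=pct)

    def test_all_failing_gives_empty_ranking(self):
        vs = [self._verdict("a", 50.0, overall=False)]
        assert rank_leads(vs) == []

    def test_higher_percentage_first(self):
        vs = [self._verdict("a", 30.0), self._verdict("b", 50.0)]
        assert [v.id for v in rank_leads(vs)] == ["b", "a"]

    def test_order_matches_independent_stable_sort(self, rng):
        vs = [
            self._verdict(f"m{i:02d}", float(rng.choice([20, 40, 60, 80])),
                          overall=bool(rng.integers(0, 2)))
            for i in range(50)
        ]
        got = [(v.id, v.pct_excellent) for v in rank_leads(vs)]
        brute = sorted(
            [(v.id, v.pct_excellent) for v in vs if v.overall_pass],
            key=lambda t: (-t[1], t[0]),
        )
        assert got == brute

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            rank_leads([])


class TestFilterOrderIndependence:
    def test_filters_commute_on_synthetic_batch(self, rng):
        # survivor set must not depend on the order the filters are applied in
        mols = []
        for i in range(60):
            mol = MoleculeRecord(
                smiles="C" * (i + 1), id=f"b{i:02d}",
                descriptors={
                    "mw": float(rng.uniform(300, 600)), "logp": float(rng.uniform(1, 7)),
                    "nhd": int(rng.integers(0, 8)), "nha": int(rng.integers(0, 13)),
                },
            )
            mols.append((mol, rng.normal(size=6)))
        panel = pd.DataFrame(
            rng.uniform(-12, -6, size=(60, 4)), columns=["DAT", "NET", "SERT", "hERG"],
            index=[m.id for m, _ in mols],
        )
        refs = [rng.normal(size=6) for _ in range(2)]

        aff = set(panel.index[affinity_filter(panel)])
        nov = {m.id for (m, z), ok in zip(mols, novelty_filter(mols, refs)) if ok}
        lip = {m.id for m, _ in mols if lipinski_filter(m)[0]}

        orders = [
            aff & nov & lip,
            lip & aff & nov,
            nov & lip & aff,
        ]
        assert orders[0] == orders[1] == orders[2]
        brute = {
            m.id for (m, z) in mols
            if m.id in aff and m.id in nov and m.id in lip
        }
        assert orders[0] == brute
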