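import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plexquant import (
    ClusterParams,
    DataError,
    IdentStageArgs,
    identify_analyte,
    identify_grid_analyte,
    identify_legendplex_analyte,
    load_panel,
)
from tests.conftest import ingest

IDS_A = ["A4", "A5", "A6", "A7", "A8", "A10"]


def apc_blobs(rng, means, n=200, sd=0.05):
    frames = []
    for i, m in enumerate(means):
        frames.append(
            pd.DataFrame({"FL6-H": rng.normal(m, sd, n), "truth": i})
        )
    df = pd.concat(frames, ignore_index=True)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


class TestIdentifyAnalyte:
    def test_lowest_intensity_blob_gets_first_id(self, rng):
        ev = apc_blobs(rng, [2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        out = identify_analyte(
            ev, "FL6-H", IDS_A, ClusterParams(method="clara", seed=0)
        )
        by_truth = out.groupby("truth")["analyte_id"].agg(lambda s: s.mode()[0])
        assert by_truth.tolist() == IDS_A
        assert out.loc[out["FL6-H"].idxmin(), "analyte_id"] == "A4"

    def test_reversed_id_list_reverses_assignment(self, rng):
        ev = apc_blobs(rng, [2.0, 6.0, 10.0], n=100)
        ids = ["lo", "mid", "hi"]
        fwd = identify_analyte(ev, "FL6-H", ids, ClusterParams(seed=0))
        rev = identify_analyte(ev, "FL6-H", ids[::-1], ClusterParams(seed=0))
        m = {"lo": "hi", "mid": "mid", "hi": "lo"}
        assert (rev["analyte_id"] == fwd["analyte_id"].map(m)).all()

    def test_trim_fraction_leaves_expected_labelled_count(self, rng):
        ev = apc_blobs(rng, [2.0, 10.0], n=1000)
        out = identify_analyte(
            ev, "FL6-H", ["x", "y"], ClusterParams(method="clara", trim=0.03, seed=0)
        )
        counts = out["analyte_id"].value_counts()
        assert counts["x"] == 970 and counts["y"] == 970
        assert out["analyte_id"].isna().sum() == 60

    def test_cluster_count_mismatch_states_both_counts(self, rng):
        ev = apc_blobs(rng, [2.0, 10.0], n=50)
        with pytest.raises(DataError, match="2 clusters"):
            identify_analyte(
                ev,
                "FL6-H",
                ["a", "b", "c"],
                ClusterParams(method="dbscan", eps=0.5, min_pts=5),
            )

    def test_monotone_transform_leaves_assignment_unchanged(self, rng):
        ev = apc_blobs(rng, [1.0, 4.0, 8.0], n=150)
        params = ClusterParams(method="clara", seed=3)
        base = identify_analyte(ev, "FL6-H", ["a", "b", "c"], params)
        warped = ev.copy()
        warped["FL6-H"] = np.sinh(warped["FL6-H"] / 2.0)  # strictly monotone
        out = identify_analyte(warped, "FL6-H", ["a", "b", "c"], params)
        assert (out["analyte_id"] == base["analyte_id"]).all()

    def test_assigned_plus_missing_equals_input(self, rng):
        ev = apc_blobs(rng, [2.0, 10.0], n=333)
        out = identify_analyte(
            ev, "FL6-H", ["x", "y"], ClusterParams(trim=0.01, seed=0)
        )
        assert out["analyte_id"].notna().sum() + out["analyte_id"].isna().sum() == len(ev)


class TestLegendplexTwoStage:
    def test_default_synthetic_yields_6_plus_7_analytes(self, default_truth_small):
        truth, samples = default_truth_small
        events = pd.concat(
            [df.assign(sample_id=n) for n, df in ingest(samples).items()],
            ignore_index=True,
        )
        out = identify_legendplex_analyte(events, truth.panel)
        assert set(out["bead_group"].dropna()) == {"A", "B"}
        in_a = out.loc[out["bead_group"] == "A", "analyte_id"].dropna()
        in_b = out.loc[out["bead_group"] == "B", "analyte_id"].dropna()
        assert set(in_a) == set(truth.panel.analytes_in("A"))
        assert set(in_b) == set(truth.panel.analytes_in("B"))

    def test_scatter_trim_fraction_unlabelled(self, rng):
        n = 10_000
        half = n // 2
        ev = pd.DataFrame(
            {
                "FSC-A": np.r_[rng.normal(4.2e5, 1e4, half), rng.normal(5.0e5, 1e4, half)],
                "SSC-A": np.r_[rng.normal(5.0e5, 2e4, half), rng.normal(7.5e5, 2e4, half)],
                "FL6-H": np.r_[rng.normal(5, 0.1, half), rng.normal(9, 0.1, half)],
            }
        )
        panel = load_panel("Growth Factor")
        scatter = IdentStageArgs(
            parameters=("FSC-A", "SSC-A"),
            column_name="bead_group",
            params=ClusterParams(method="clara", trim=0.01, seed=0),
        )
        reporter = IdentStageArgs(
            parameters=("FL6-H",),
            column_name="analyte_id",
            params=ClusterParams(method="clara", trim=0.0, seed=1),
        )
        # 2 scatter groups but each carries only one APC blob here, so
        # only exercise the scatter stage via identify_analyte
        from plexquant import identify_analyte

        out = identify_analyte(
            ev, ("FSC-A", "SSC-A"), ["A", "B"], scatter.params, column_name="bead_group"
        )
        assert out["bead_group"].isna().sum() == 100  # exactly 1%

    def test_group_label_recovery_against_truth(self, default_truth_small):
        truth, samples = default_truth_small
        events = pd.concat(
            [df.assign(sample_id=n) for n, df in ingest(samples).items()],
            ignore_index=True,
        )
        out = identify_legendplex_analyte(events, truth.panel)
        mask = out["analyte_id"].notna()
        ari = adjusted_rand_score(
            out.loc[mask, "true_analyte_id"], out.loc[mask, "analyte_id"]
        )
        assert ari >= 0.99
        frac_correct = (
            out.loc[mask, "analyte_id"] == out.loc[mask, "true_analyte_id"]
        ).mean()
        assert frac_correct >= 0.95

    def test_pooled_equals_per_sample_for_identical_populations(
        self, default_truth_small
    ):
        truth, samples = default_truth_small
        ingested = ingest(samples)
        two = {k: ingested[k] for k in list(ingested)[:2]}
        events = pd.concat(
            [df.assign(sample_id=n) for n, df in two.items()], ignore_index=True
        )
        pooled = identify_legendplex_analyte(events, truth.panel)
        per_sample = pd.concat(
            [
                identify_legendplex_analyte(
                    df.assign(sample_id=n), truth.panel
                )
                for n, df in two.items()
            ],
            ignore_index=True,
        )
        # clusters are identical by construction: compare modal ID per
        # true analyte rather than per-event trim decisions
        agree = (
            pooled.groupby("true_analyte_id")["analyte_id"].agg(lambda s: s.mode()[0])
            == per_sample.groupby("true_analyte_id")["analyte_id"].agg(
                lambda s: s.mode()[0]
            )
        )
        assert agree.all()


class TestGridIdent:
    def grid_events(self, rng, centers, n=120):
        frames = [
            pd.DataFrame(
                {
                    "APC": rng.normal(cx, 0.05, n),
                    "APC-Cy7": rng.normal(cy, 0.05, n),
                    "truth": f"{cx}:{cy}",
                }
            )
            for cx, cy in centers
        ]
        df = pd.concat(frames, ignore_index=True)
        return df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    def test_2x2_grid_row_major_assignment(self, rng):
        ev = self.grid_events(rng, [(0, 0), (0, 2), (2, 0), (2, 2)])
        out = identify_grid_analyte(
            ev,
            ("APC", "APC-Cy7"),
            [["r0c0", "r0c1"], ["r1c0", "r1c1"]],
            ClusterParams(method="kmeans", seed=0),
        )
        modal = out.groupby("truth")["analyte_id"].agg(lambda s: s.mode()[0])
        assert modal["0:0"] == "r0c0"
        assert modal["0:2"] == "r0c1"
        assert modal["2:0"] == "r1c0"
        assert modal["2:2"] == "r1c1"

    def test_single_row_grid_ranks_on_second_channel(self, rng):
        ev = self.grid_events(rng, [(5, 0), (5, 2), (5, 4)])
        out = identify_grid_analyte(
            ev,
            ("APC", "APC-Cy7"),
            [["lo", "mid", "hi"]],
            ClusterParams(method="kmeans", seed=0),
        )
        modal = out.groupby("truth")["analyte_id"].agg(lambda s: s.mode()[0])
        assert modal["5:0"] == "lo" and modal["5:4"] == "hi"

    def test_cell_count_mismatch_errors(self, rng):
        ev = self.grid_events(rng, [(0, 0), (2, 2)])
        with pytest.raises(DataError, match="clusters"):
            identify_grid_analyte(
                ev,
                ("APC", "APC-Cy7"),
                [["a", "b", "c"]],
                ClusterParams(method="dbscan", eps=0.3, min_pts=5),
            )
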