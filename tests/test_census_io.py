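import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from harvestvar import census_io
from harvestvar.census_io import (CensusSeries, read_census, read_sizes,
                                  to_long, write_census, write_sizes)
from harvestvar.cli import main as cli_main
from harvestvar.exceptions import ValidationError
from harvestvar.sizes import make_size_fixture


class TestCensusRoundtrip:
    def test_roundtrip_identity(self, small_experiment, tmp_path):
        path = tmp_path / "census.csv"
        write_census(small_experiment, path)
        back = read_census(path)
        assert len(back) == len(small_experiment)
        orig = {s.tube: s for s in small_experiment}
        for s in back:
            o = orig[s.tube]
            assert (s.environment, s.harvest) == (o.environment, o.harvest)
            pd.testing.assert_frame_equal(
                s.counts, o.counts[s.counts.columns], check_dtype=False)

    def test_write_is_deterministic(self, small_experiment, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_census(small_experiment, p1)
        write_census(small_experiment, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_census([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == ["week", "tube", "environment", "harvest",
                                       "stage", "count", "harvested"]

    def test_long_layout_row_count(self, small_experiment):
        long = to_long(small_experiment)
        # tubes x weeks x 3 stages
        assert len(long) == len(small_experiment) * 30 * 3

    def test_wide_layout_accepted(self, small_experiment, tmp_path):
        s = small_experiment[0]
        wide = s.counts.assign(tube=s.tube, environment=s.environment,
                               harvest=s.harvest)
        path = tmp_path / "wide.csv"
        wide.to_csv(path, index=False)
        back = read_census(path)
        assert len(back) == 1
        assert back[0].counts["adults"].tolist() == s.counts["adults"].tolist()

    def test_column_mapping_for_foreign_headers(self, small_experiment, tmp_path):
        s = small_experiment[0]
        foreign = s.counts.assign(tube=s.tube, environment=s.environment,
                                  harvest=s.harvest)
        foreign = foreign.rename(columns={"week": "census_week", "adults": "n_adult"})
        path = tmp_path / "foreign.csv"
        foreign.to_csv(path, index=False)
        back = read_census(path, column_map={"census_week": "week", "n_adult": "adults"})
        assert back[0].counts["adults"].tolist() == s.counts["adults"].tolist()


class TestCensusValidation:
    def _frame(self, **overrides):
        df = pd.DataFrame({
            "week": [1, 2], "tube": ["t1", "t1"], "environment": ["constant"] * 2,
            "harvest": ["none"] * 2, "eggs": [5, 6], "juveniles": [7, 8],
            "adults": [9, 10], "harvested": [0, 0]})
        for k, v in overrides.items():
            df[k] = v
        return df

    @pytest.mark.parametrize("overrides", [
        {"harvested": [10, 0]},            # harvested > adults
        {"adults": [-1, 10]},              # negative count
        {"environment": ["lunar"] * 2},    # unknown label
        {"week": [1, 1]},                  # duplicate (tube, week)
        {"week": [0, 1]},                  # week < 1
    ])
    def test_invariant_breaches_rejected(self, overrides, tmp_path):
        path = tmp_path / "bad.csv"
        self._frame(**overrides).to_csv(path, index=False)
        with pytest.raises(ValidationError) as err:
            read_census(path)
        assert err.value.rows  # offending rows are reported

    def test_missing_weeks_warn(self, tmp_path):
        df = self._frame()
        df["week"] = [1, 3]
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="missing weeks"):
            read_census(path)


class TestSizes:
    def _fixture(self):
        return make_size_fixture([
            {"tube": "t1", "week": 60, "stage": "female_adult",
             "mean_log": np.log(625), "sd_log": 0.08, "n": 40},
            {"tube": "t1", "week": 60, "stage": "juvenile",
             "mean_log": np.log(285), "sd_log": 0.12, "n": 40},
        ], seed=1)

    def test_roundtrip(self, tmp_path):
        df = self._fixture()
        path = tmp_path / "sizes.csv"
        write_sizes(df, path)
        back = read_sizes(path)
        assert len(back) == len(df)
        assert set(back["stage"]) == {"female_adult", "juvenile"}

    def test_nonpositive_length_rejected(self, tmp_path):
        df = self._fixture()
        df.loc[0, "length_um"] = -5.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_sizes(path)

    def test_stage_vocabulary_enforced(self, tmp_path):
        df = self._fixture()
        df.loc[0, "stage"] = "larva"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_sizes(path)


class TestCLI:
    def test_simulate_writes_census(self, tmp_path):
        cfg = tmp_path / "c.json"
        cfg.write_text('{"design": {"n_replicates": 2, "n_weeks": 15, '
                       '"master_seed": 3, "treatments": [["constant", "none"]]}}')
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", str(cfg),
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        series = read_census(tmp_path / "out" / "census.csv")
        assert len(series) == 2 and len(series[0].counts) == 15

    def test_analyze_window_produces_summary(self, tmp_path, small_experiment):
        census = tmp_path / "census.csv"
        write_census(small_experiment, census)
        runner = CliRunner()
        out = tmp_path / "summary.csv"
        res = runner.invoke(cli_main, [
            "analyze-window", "--census", str(census), "--weeks", "10", "25",
            "--bootstrap", "200", "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out)
        assert {"environment", "harvest", "estimate", "ci_lo", "ci_hi"} <= set(table.columns)
        assert len(table) == 7

    def test_missing_config_is_an_error(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", "absent.json",
                                       "--out", "x"])
        assert res.exit_code != 0

    def test_cli_entry_point_reexported(self):
        assert callable(census_io.cli)
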