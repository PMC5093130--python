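"""Precursor partitioning, cargo calls and the homolog filter."""

import pytest

from heveinscan import (
    FilterCriteria,
    PrecursorRecord,
    cargo_classification,
    filter_homologs,
    multi_plant_groups,
    paper_fixture,
    partition_domains,
    unique_mature_domains,
)
from heveinscan.synthetic_data import GeneratorConfig, generate_precursor


class TestPartition:
    def test_generator_ground_truth_recovered(self):
        rec, truth = generate_precursor(GeneratorConfig(), seed=7)
        part = partition_domains(rec.full_sequence, rec.id)
        assert part.signal == rec.full_sequence[: truth.sig_end]
        assert part.mature == rec.full_sequence[truth.sig_end : truth.mat_end]
        assert part.c_tail == rec.full_sequence[truth.mat_end :]

    def test_recovery_rate_on_default_records(self):
        """Rule-based boundaries match generator truth in >= 99% of records."""
        ok = 0
        n = 300
        for i in range(n):
            rec, truth = generate_precursor(GeneratorConfig(), seed=i)
            part = partition_domains(rec.full_sequence, rec.id)
            ok += part.partitioned and len(part.signal) == truth.sig_end and \
                len(part.signal) + len(part.mature) == truth.mat_end
        assert ok / n >= 0.99

    def test_gly_asp_cleavage_site(self):
        seq = "M" + "L" * 17 + "AAG" + "DPTC" + "A" * 20
        part = partition_domains(seq, "x")
        assert part.signal is not None
        assert part.signal.endswith("G")
        assert part.mature.startswith("D")
        assert len(part.signal) == 21

    def test_no_site_yields_diagnostic(self):
        part = partition_domains("A" * 60, "x")
        assert not part.partitioned
        assert "no GD site" in part.cleavage_rule_used or "no G" in part.cleavage_rule_used

    def test_annotation_used_verbatim(self):
        seq = "A" * 60
        part = partition_domains(seq, "x", annotation=(20, 55))
        assert (len(part.signal), len(part.mature), len(part.c_tail)) == (20, 35, 5)

    def test_domains_concatenate(self):
        rec, _ = generate_precursor(GeneratorConfig(), seed=3)
        assert rec.signal + rec.mature + rec.c_tail == rec.full_sequence


class TestCargo:
    @pytest.mark.parametrize("n,status", [(20, "cargo_free"), (126, "cargo"),
                                          (254, "cargo"), (50, "cargo"), (49, "cargo_free")])
    def test_threshold(self, n, status):
        rec = PrecursorRecord("x", "A" * (30 + n), signal="A" * 5,
                              mature="A" * 25, c_tail="A" * n)
        assert cargo_classification(rec).status == status

    def test_unset_tail_rejected(self):
        with pytest.raises(ValueError):
            cargo_classification(PrecursorRecord("x", "AAAA"))

    @pytest.mark.parametrize("mode,n", [("short", 20), ("barwin", 126), ("chitinase", 254)])
    def test_generator_tail_modes(self, mode, n):
        rec, _ = generate_precursor(GeneratorConfig(c_tail_mode=mode), seed=1)
        call = cargo_classification(rec)
        assert call.c_tail_length == n
        assert call.status == ("cargo_free" if mode == "short" else "cargo")


class TestFilter:
    def test_screen_replication(self):
        """85 candidates -> 52 survivors with removals (1,3,3,9,17) -> 42 peptides."""
        records, _ = paper_fixture(seed=11)
        survivors, report = filter_homologs(records)
        assert report.input_count == 85
        assert len(survivors) == 52
        assert report.removed_counts == {
            "odd_cys": 1,
            "short_signal": 3,
            "undetermined": 3,
            "duplicate_same_plant": 9,
            "missing_pro_flanks": 17,
        }
        groups = unique_mature_domains(survivors)
        assert len(groups) == 42
        multi = multi_plant_groups(groups)
        assert len(multi) == 6
        assert sorted(len(groups[m]) for m in multi) == [2, 2, 2, 2, 2, 6]

    def test_conservation(self):
        records, _ = paper_fixture(seed=2)
        survivors, report = filter_homologs(records)
        assert len(survivors) + sum(report.removed_counts.values()) == len(records)
        assert not set(report.survivors) & {
            i for ids in report.removed.values() for i in ids
        }

    def test_idempotence(self):
        records, _ = paper_fixture(seed=2)
        survivors, _ = filter_homologs(records)
        again, report = filter_homologs(survivors)
        assert [r.id for r in again] == [r.id for r in survivors]
        assert sum(report.removed_counts.values()) == 0

    def test_empty_input(self):
        survivors, report = filter_homologs([])
        assert survivors == [] and report.input_count == 0
        assert sum(report.removed_counts.values()) == 0

    def test_all_passing_identity(self):
        records, truths = paper_fixture(seed=5)
        passing = [r for r, t in zip(records, truths) if t.decoy_category is None]
        survivors, _ = filter_homologs(passing)
        assert survivors == passing

    def test_attribution_is_first_match(self):
        """A record violating two criteria is counted under the earlier one."""
        rec, _ = generate_precursor(GeneratorConfig(), seed=9)
        mature = rec.mature[:5] + "X" + rec.mature[6:]
        bad = PrecursorRecord(
            "bad", "AG" + mature + rec.c_tail, organism=rec.organism,
            signal="AG", mature=mature, c_tail=rec.c_tail,  # short signal AND an X
        )
        _, report = filter_homologs([bad])
        assert report.removed["short_signal"] == ["bad"]

    def test_duplicate_keeps_first_in_input_order(self):
        rec, _ = generate_precursor(GeneratorConfig(), seed=4)
        a = PrecursorRecord("first", rec.full_sequence, organism="Pinus taeda",
                            signal=rec.signal, mature=rec.mature, c_tail=rec.c_tail)
        b = PrecursorRecord("second", rec.full_sequence, organism="Pinus taeda",
                            signal=rec.signal, mature=rec.mature, c_tail=rec.c_tail)
        survivors, report = filter_homologs([a, b])
        assert [r.id for r in survivors] == ["first"]
        assert report.removed["duplicate_same_plant"] == ["second"]
        survivors, report = filter_homologs([b, a])
        assert [r.id for r in survivors] == ["second"]

    def test_same_sequence_other_plant_kept(self):
        rec, _ = generate_precursor(GeneratorConfig(), seed=4)
        a = PrecursorRecord("a", rec.full_sequence, organism="Pinus taeda",
                            signal=rec.signal, mature=rec.mature, c_tail=rec.c_tail)
        b = PrecursorRecord("b", rec.full_sequence, organism="Picea abies",
                            signal=rec.signal, mature=rec.mature, c_tail=rec.c_tail)
        survivors, _ = filter_homologs([a, b])
        assert len(survivors) == 2

    def test_criteria_order_changes_attribution_not_survivors(self):
        """Permuting content criteria reshuffles counts, not the survivor set."""
        records, truths = paper_fixture(seed=3)
        no_dups = [r for r, t in zip(records, truths)
                   if t.decoy_category != "duplicate_same_plant"]
        # add a record violating two criteria so attribution can move
        src = no_dups[0]
        mature = src.mature[:5] + "X" + src.mature[6:]
        no_dups.append(PrecursorRecord(
            "impure", "AG" + mature + src.c_tail, organism=src.organism,
            signal="AG", mature=mature, c_tail=src.c_tail,
        ))
        base, base_rep = filter_homologs(no_dups)
        permuted = FilterCriteria(order=(
            "missing_pro_flanks", "undetermined", "short_signal",
            "odd_cys", "duplicate_same_plant",
        ))
        alt, alt_rep = filter_homologs(no_dups, permuted)
        assert {r.id for r in alt} == {r.id for r in base}
        assert alt_rep.removed_counts != base_rep.removed_counts
        assert "impure" in base_rep.removed["short_signal"]
        assert "impure" in alt_rep.removed["undetermined"]


class TestUniqueDomains:
    def test_all_distinct(self):
        recs = [PrecursorRecord(f"r{i}", f"AAG{'D'+'A'*i}", mature=f"D{'A'*i}",
                                signal="AAG", c_tail="") for i in range(1, 6)]
        assert len(unique_mature_domains(recs)) == 5

    def test_shared_domain_groups(self):
        kw = dict(signal="AAG", mature="DAC", c_tail="")
        a = PrecursorRecord("a", "AAGDAC", organism="Pinus taeda", **kw)
        b = PrecursorRecord("b", "AAGDAC", organism="Picea abies", **kw)
        groups = unique_mature_domains([a, b])
        assert len(groups) == 1
        assert len(multi_plant_groups(groups)["DAC"]) == 2

    def test_unset_mature_rejected(self):
        with pytest.raises(ValueError, match="r0"):
            unique_mature_domains([PrecursorRecord("r0", "AAAA")])
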