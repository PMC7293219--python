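"""Database simulator: access cycle, toehold operations, metrics."""

import math

import numpy as np
import pytest

from doriskit import (
    AccessParams,
    Database,
    StrandState,
    build_ssdsdna,
    compute_metrics,
    delete,
    ivt,
    lock,
    make_lock,
    make_rename_oligo,
    make_template,
    min_initial_copies,
    rename,
    repeat_access,
    return_file,
    reverse_complement,
    separate,
    unlock,
)
from doriskit.sequences import FileRecord, effective_address
from doriskit.simulate import (
    DEFAULT_CAPTURED_SURVIVAL,
    DEFAULT_IVT_LOSS_RATE,
    DEFAULT_PER_ACCESS_RETENTION,
    DEFAULT_SEPARATION_PROBABILITY,
    FileOperationError,
    TruncatedProduct,
)

ADDR_A = "ACGTACGTACGTACGTACGT"
ADDR_B = "TGCATGCATGCATGCATGCA"
ADDR_C = "GGATCCGGATCCGGATCCGG"


def make_strand(address: str, payload_seed: int = 0):
    rng = np.random.default_rng(payload_seed)
    payload = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 117)])
    return build_ssdsdna(make_template(payload, address))


def make_db(copies: int = 1000, seed: int = 0) -> Database:
    files = {}
    for i, addr in enumerate((ADDR_A, ADDR_B, ADDR_C)):
        frec = FileRecord(address=addr)
        for j in range(2):
            frec.add(f"f{i}s{j}", make_strand(addr, payload_seed=10 * i + j), copies)
        files[addr] = frec
    return Database(files=files, rng_seed=seed)


class TestCalibration:
    def test_defaults_compose_to_published_retention(self):
        expected = (
            DEFAULT_SEPARATION_PROBABILITY * DEFAULT_CAPTURED_SURVIVAL
            + (1 - DEFAULT_SEPARATION_PROBABILITY)
        )
        assert expected == pytest.approx(DEFAULT_PER_ACCESS_RETENTION)
        assert (1 - DEFAULT_IVT_LOSS_RATE) ** 8 == pytest.approx(
            DEFAULT_CAPTURED_SURVIVAL
        )

    def test_params_validated(self):
        with pytest.raises(ValueError, match="separation_probability"):
            AccessParams(separation_probability=1.5)
        with pytest.raises(ValueError, match="ivt_hours"):
            AccessParams(ivt_hours=-1)
        with pytest.raises(ValueError, match="absolute zero"):
            AccessParams(temperature_celsius=-300)


class TestSeparate:
    def test_copy_conservation(self):
        db = make_db()
        rng = np.random.default_rng(7)
        retained, bound = separate(
            db, reverse_complement(ADDR_A), AccessParams(), rng=rng
        )
        total_before = sum(db.total_copies().values())
        total_after = sum(retained.total_copies().values()) + bound.total_copies()
        assert total_after == total_before

    def test_only_target_file_captured(self):
        db = make_db()
        rng = np.random.default_rng(7)
        _, bound = separate(db, reverse_complement(ADDR_A), AccessParams(), rng=rng)
        target_ids = set(db.files[ADDR_A].strands)
        assert set(bound.strands) <= target_ids
        assert bound.total_copies() > 0

    def test_capture_rate_near_separation_probability(self):
        db = make_db(copies=20_000)
        rng = np.random.default_rng(3)
        _, bound = separate(db, reverse_complement(ADDR_B), AccessParams(), rng=rng)
        frac = bound.total_copies() / db.files[ADDR_B].total_copies()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_certain_capture_with_unit_probability(self):
        db = make_db(copies=50)
        params = AccessParams(separation_probability=1.0)
        _, bound = separate(
            db, reverse_complement(ADDR_A), params, rng=np.random.default_rng(0)
        )
        assert bound.total_copies() == db.files[ADDR_A].total_copies()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            separate(make_db(), reverse_complement(ADDR_A), AccessParams(), mode="qpcr")

    def test_pcr_mode_logs_truncated_products_for_internal_sites(self):
        addr = ADDR_A
        site = reverse_complement(addr)
        # plant the priming site inside the payload as well
        payload = ("ACGT" * 30)[:117]
        payload = payload[:40] + site + payload[40 + 20 :]
        strand = build_ssdsdna(make_template(payload, addr))
        frec = FileRecord(address=addr)
        frec.add("s0", strand, 100)
        db = Database(files={addr: frec})
        retained, _ = separate(
            db, site, AccessParams(), mode="PCR", rng=np.random.default_rng(0)
        )
        events = [e for e in retained.log if e.get("event") == "truncated_product"]
        assert events
        assert isinstance(events[0]["record"], TruncatedProduct)

    def test_doris_mode_ignores_internal_sites(self):
        addr = ADDR_A
        site = reverse_complement(addr)
        payload = ("ACGT" * 30)[:117]
        payload = payload[:40] + site + payload[40 + 20 :]
        strand = build_ssdsdna(make_template(payload, addr))
        frec = FileRecord(address=addr)
        frec.add("s0", strand, 100)
        db = Database(files={addr: frec})
        retained, _ = separate(
            db, site, AccessParams(), mode="DORIS", rng=np.random.default_rng(0)
        )
        assert not any(
            e.get("event") == "truncated_product" for e in retained.log
        )


class TestIVT:
    def test_transcripts_are_rna_complement_of_payload(self):
        strand = make_strand(ADDR_A)
        frec = FileRecord(address=ADDR_A)
        frec.add("s0", strand, 50)
        transcripts, _ = ivt(frec, AccessParams(), np.random.default_rng(1))
        lo, hi = strand.layout.payload_interval
        expected = reverse_complement(strand.template[lo:hi]).replace("T", "U")
        assert transcripts[0].sequence == expected
        assert set(expected) <= set("ACGU")

    def test_zero_hours_no_loss_no_transcripts(self):
        frec = FileRecord(address=ADDR_A)
        frec.add("s0", make_strand(ADDR_A), 500)
        params = AccessParams(ivt_hours=0.0)
        transcripts, surviving = ivt(frec, params, np.random.default_rng(1))
        assert transcripts == []
        assert surviving.total_copies() == 500

    def test_survival_matches_decay_law(self):
        frec = FileRecord(address=ADDR_A)
        frec.add("s0", make_strand(ADDR_A), 100_000)
        params = AccessParams()
        _, surviving = ivt(frec, params, np.random.default_rng(5))
        frac = surviving.total_copies() / 100_000
        assert frac == pytest.approx(0.74, abs=0.01)

    def test_transcript_counts_scale_with_copies_and_hours(self):
        frec = FileRecord(address=ADDR_A)
        frec.add("s0", make_strand(ADDR_A), 1000)
        p1 = AccessParams(ivt_hours=2.0)
        p2 = AccessParams(ivt_hours=8.0)
        t1, _ = ivt(frec, p1, np.random.default_rng(2))
        t2, _ = ivt(frec, p2, np.random.default_rng(2))
        assert t2[0].count > 2 * t1[0].count


class TestReturnAndRepeat:
    def test_full_elution_round_trip_conserves_copies(self):
        db = make_db(copies=400)
        rng = np.random.default_rng(11)
        params = AccessParams(elution_efficiency=1.0)
        retained, bound = separate(db, reverse_complement(ADDR_A), params, rng=rng)
        restored = return_file(retained, bound, params, rng=rng)
        assert restored.total_copies() == db.total_copies()

    def test_returned_strands_are_exposed(self):
        db = make_db(copies=400)
        rng = np.random.default_rng(11)
        params = AccessParams()
        retained, bound = separate(db, reverse_complement(ADDR_A), params, rng=rng)
        restored = return_file(retained, bound, params, rng=rng)
        for strand in restored.files[ADDR_A].strands.values():
            assert strand.state is StrandState.EXPOSED

    def test_repeat_access_retention_table(self):
        db = make_db(copies=50_000, seed=21)
        _, table = repeat_access(
            db, ADDR_A, 5, AccessParams(), np.random.default_rng(21)
        )
        assert list(table.index) == [0, 1, 2, 3, 4, 5]
        assert table.loc[0, ADDR_A] == 100.0
        # accessed file decays, untouched files stay at 100%
        col = table[ADDR_A].to_numpy()
        assert all(a > b for a, b in zip(col, col[1:]))
        assert table.loc[5, ADDR_A] == pytest.approx(100 * 0.87**5, abs=2.0)
        assert (table[ADDR_B] == 100.0).all()
        assert (table[ADDR_C] == 100.0).all()

    def test_negative_cycles_rejected(self):
        with pytest.raises(ValueError):
            repeat_access(make_db(), ADDR_A, -1, AccessParams())


class TestMinInitialCopies:
    def test_published_operating_point(self):
        assert min_initial_copies(5, 0.87) == 2

    def test_monotone_in_accesses(self):
        vals = [min_initial_copies(n, 0.87) for n in range(0, 30, 5)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_zero_accesses_needs_one_copy(self):
        assert min_initial_copies(0) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_initial_copies(-1)
        with pytest.raises(ValueError):
            min_initial_copies(5, 0.0)


class TestToeholdOperations:
    def _file(self, copies: int = 100) -> FileRecord:
        frec = FileRecord(address=ADDR_A)
        frec.add("s0", make_strand(ADDR_A), copies)
        return frec

    def test_lock_geometry(self):
        lk = make_lock(ADDR_A)
        assert len(lk) == 50
        assert lk.endswith(reverse_complement(ADDR_A))

    def test_rename_geometry(self):
        ro = make_rename_oligo(ADDR_A, ADDR_B)
        assert len(ro) == 40
        assert ro == ADDR_B + reverse_complement(ADDR_A)

    def test_locked_file_not_captured_below_melt(self):
        locked = lock(self._file(), make_lock(ADDR_A), add_temperature_celsius=98)
        db = Database(files={ADDR_A: locked})
        _, bound = separate(
            db,
            reverse_complement(ADDR_A),
            AccessParams(temperature_celsius=25.0),
            rng=np.random.default_rng(0),
        )
        assert bound.total_copies() == 0

    def test_leaky_lock_captures_small_fraction(self):
        locked = lock(
            self._file(copies=100_000),
            make_lock(ADDR_A),
            add_temperature_celsius=25,
        )
        db = Database(files={ADDR_A: locked})
        _, bound = separate(
            db,
            reverse_complement(ADDR_A),
            AccessParams(temperature_celsius=25.0),
            rng=np.random.default_rng(0),
        )
        frac = bound.total_copies() / 100_000
        assert frac == pytest.approx(0.5 * 0.05, abs=0.005)

    def test_lock_melts_above_threshold(self):
        locked = lock(self._file(copies=1000), make_lock(ADDR_A), 98)
        db = Database(files={ADDR_A: locked})
        _, bound = separate(
            db,
            reverse_complement(ADDR_A),
            AccessParams(temperature_celsius=60.0, separation_probability=1.0),
            rng=np.random.default_rng(0),
        )
        assert bound.total_copies() == 1000

    def test_unlock_restores_access(self):
        lk = make_lock(ADDR_A)
        locked = lock(self._file(), lk, 98)
        unlocked = unlock(locked, reverse_complement(lk))
        for strand in unlocked.strands.values():
            assert strand.state is StrandState.EXPOSED
            assert not strand.attachments
        db = Database(files={ADDR_A: unlocked})
        _, bound = separate(
            db,
            reverse_complement(ADDR_A),
            AccessParams(separation_probability=1.0),
            rng=np.random.default_rng(0),
        )
        assert bound.total_copies() == unlocked.total_copies()

    def test_wrong_key_warns_and_leaves_locked(self):
        locked = lock(self._file(), make_lock(ADDR_A), 98)
        with pytest.warns(UserWarning, match="remains locked"):
            still = unlock(locked, "A" * 50)
        assert all(
            s.state is StrandState.LOCKED for s in still.strands.values()
        )

    def test_lock_requires_complement(self):
        with pytest.raises(FileOperationError, match="complementary"):
            lock(self._file(), "A" * 50, 98)

    def test_rename_switches_answering_address(self):
        renamed = rename(self._file(), make_rename_oligo(ADDR_A, ADDR_B))
        assert renamed.address == ADDR_B
        for strand in renamed.strands.values():
            assert effective_address(strand) == ADDR_B
        db = Database(files={ADDR_B: renamed})
        params = AccessParams(separation_probability=1.0)
        _, bound_old = separate(
            db, reverse_complement(ADDR_A), params, rng=np.random.default_rng(0)
        )
        _, bound_new = separate(
            db, reverse_complement(ADDR_B), params, rng=np.random.default_rng(0)
        )
        assert bound_old.total_copies() == 0
        assert bound_new.total_copies() == renamed.total_copies()

    def test_rename_wrong_length_or_mismatch(self):
        with pytest.raises(FileOperationError, match="40 nt"):
            rename(self._file(), "ACGT")
        with pytest.raises(FileOperationError, match="old-address"):
            rename(self._file(), "A" * 40)

    def test_delete_blocks_all_capture(self):
        blocked = delete(self._file(), reverse_complement(ADDR_A))
        db = Database(files={ADDR_A: blocked})
        _, bound = separate(
            db,
            reverse_complement(ADDR_A),
            AccessParams(separation_probability=1.0),
            rng=np.random.default_rng(0),
        )
        assert bound.total_copies() == 0

    def test_delete_requires_matching_oligo(self):
        with pytest.raises(FileOperationError, match="does not match"):
            delete(self._file(), "A" * 20)

    def test_lock_refuses_non_exposed_strands(self):
        blocked = delete(self._file(), reverse_complement(ADDR_A))
        with pytest.raises(FileOperationError, match="no exposed overhang"):
            lock(blocked, make_lock(ADDR_A), 98)


class TestMetrics:
    def test_deterministic_bookkeeping(self):
        db = make_db(copies=100)
        params = AccessParams(separation_probability=1.0, elution_efficiency=1.0)
        rng = np.random.default_rng(0)
        retained, bound = separate(db, reverse_complement(ADDR_A), params, rng=rng)
        after = return_file(retained, bound, params, rng=rng)
        report = compute_metrics(db, bound, after)
        assert report.file_specificity[ADDR_A] == pytest.approx(100.0)
        assert report.file_specificity[ADDR_B] == pytest.approx(0.0)
        assert report.separation_efficiency[ADDR_A] == pytest.approx(100.0)
        assert report.retention_rate[ADDR_A] == pytest.approx(100.0)
        assert all(
            v == pytest.approx(1.0) for v in report.normalized_abundance.values()
        )

    def test_zero_denominators_are_none(self):
        empty = Database(files={ADDR_A: FileRecord(address=ADDR_A)})
        report = compute_metrics(empty, FileRecord(address=ADDR_A), empty)
        assert report.file_specificity[ADDR_A] is None
        assert report.separation_efficiency[ADDR_A] is None
        assert report.retention_rate[ADDR_A] is None
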