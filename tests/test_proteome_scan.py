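"""FASTA ingestion, protein statistics, proteome scanning and report
writers."""

import pytest
from Bio.SeqUtils import molecular_weight

from cyclasescan import (
    ProteinRecord,
    builtin_catalog,
    protein_stats,
    read_fasta,
    scan_proteome,
    write_fasta,
    write_gff3,
    write_tsv,
)
from cyclasescan.scan import FastaFormatError, read_tsv


class TestReadFasta:
    def test_wrapped_sequences_are_concatenated(self, fasta_file):
        path = fasta_file(
            [("p1", "first protein", "MKV" * 50), ("p2", "", "GAVLI" * 30)]
        )
        records = read_fasta(path)
        assert [r.id for r in records] == ["p1", "p2"]
        assert records[0].sequence == "MKV" * 50
        assert records[0].description == "first protein"
        assert records[1].sequence == "GAVLI" * 30

    def test_lowercase_and_trailing_stop_normalized(self, tmp_path):
        path = tmp_path / "f.fasta"
        path.write_text(">p1\nmkvga*\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "MKVGA"

    def test_non_fasta_leading_content_rejected(self, tmp_path):
        path = tmp_path / "f.fasta"
        path.write_text("MKVGA\n>p1\nMKV\n")
        with pytest.raises(FastaFormatError, match="not FASTA"):
            read_fasta(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "f.fasta"
        path.write_text(">p1\nMKV\n>p1\nGAV\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            read_fasta(path)

    def test_empty_sequence_rejected(self, tmp_path):
        path = tmp_path / "f.fasta"
        path.write_text(">p1\n\n>p2\nMKV\n")
        with pytest.raises(FastaFormatError, match="empty"):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            read_fasta(tmp_path / "absent.fasta")

    def test_write_read_round_trip(self, tmp_path, rng):
        records = [
            ProteinRecord(
                id=f"p{i}",
                description=f"protein {i}",
                sequence="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 137)),
            )
            for i in range(3)
        ]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records

    def test_crlf_input_accepted(self, tmp_path):
        path = tmp_path / "f.fasta"
        path.write_bytes(b">p1 desc\r\nMKVGA\r\nMKVGA\r\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "MKVGAMKVGA"


class TestProteinStats:
    def test_fragment_length_arithmetic(self):
        record = ProteinRecord("p", "", "A" * 1146)
        stats = protein_stats(record, (834, 1146))
        assert stats.length == 313

    def test_single_glycine_mass(self):
        stats = protein_stats(ProteinRecord("p", "", "G"))
        assert stats.average_mass == pytest.approx(75.07, abs=0.01)

    def test_mass_agrees_with_biopython(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 313))
        stats = protein_stats(ProteinRecord("p", "", seq))
        reference = molecular_weight(seq, seq_type="protein", monoisotopic=False)
        assert stats.average_mass == pytest.approx(reference, rel=1e-4)

    def test_empty_and_out_of_bounds_ranges_raise(self):
        record = ProteinRecord("p", "", "MKVGA")
        with pytest.raises(ValueError, match="start > end"):
            protein_stats(record, (4, 2))
        with pytest.raises(ValueError, match="outside"):
            protein_stats(record, (1, 6))

    def test_non_canonical_residue_named_in_error(self):
        record = ProteinRecord("p", "", "MKXGA")
        with pytest.raises(ValueError, match="'X' at position 3"):
            protein_stats(record)


def _planted_records(rng, n=6):
    catalog = builtin_catalog()
    pattern = catalog["GC_CORE_STRICT"]
    from cyclasescan import sample_realization

    records, coords = [], []
    for i in range(n):
        background = "".join(rng.choice(list("ADEN"), 120))
        pos = int(rng.integers(0, 120 - 14))
        planted = sample_realization(pattern, rng)
        seq = background[:pos] + planted + background[pos + 14 :]
        records.append(ProteinRecord(f"p{i}", "", seq))
        coords.append((f"p{i}", pos + 1, pos + 14))
    return records, coords


class TestScanProteome:
    def test_planted_candidates_recovered_at_truth_coordinates(self, rng):
        records, coords = _planted_records(rng)
        table = scan_proteome(records, [builtin_catalog()["GC_CORE_STRICT"]])
        got = [(r.seq_id, r.match.start, r.match.end) for r in table.rows]
        assert got == coords

    def test_empty_record_list(self):
        table = scan_proteome([], [builtin_catalog()["GC_CORE_STRICT"]])
        assert len(table) == 0

    def test_monocot_scan_is_superset_of_strict(self, rng):
        seqs = [
            ProteinRecord(f"s{i}", "", "".join(rng.choice(list("SYGTVFELLVCKRM"), 250)))
            for i in range(5)
        ]
        catalog = builtin_catalog()
        strict = scan_proteome(seqs, [catalog["GC_CORE_STRICT"]], max_mismatch=1)
        mono = scan_proteome(seqs, [catalog["GC_CORE_MONOCOT"]], max_mismatch=1)
        strict_keys = {(r.seq_id, r.match.start, r.match.end) for r in strict.rows}
        mono_keys = {(r.seq_id, r.match.start, r.match.end) for r in mono.rows}
        assert strict_keys <= mono_keys

    def test_require_metal_drops_unsupported_rows(self, rng):
        records, _ = _planted_records(rng)
        catalog = builtin_catalog()
        full = scan_proteome(records, [catalog["GC_CORE_STRICT"]])
        filtered = scan_proteome(
            records, [catalog["GC_CORE_STRICT"]], require_metal=True
        )
        kept = {
            (r.seq_id, r.match.start) for r in full.rows if r.match.metal.found
        }
        assert {(r.seq_id, r.match.start) for r in filtered.rows} == kept

    def test_scan_equals_union_of_single_record_scans(self, rng):
        records, _ = _planted_records(rng)
        patterns = [builtin_catalog()["GC_CORE_STRICT"]]
        whole = scan_proteome(records, patterns)
        parts = [
            row for rec in records for row in scan_proteome([rec], patterns).rows
        ]
        key = lambda r: (r.seq_id, r.match.start, r.match.end)
        assert [key(r) for r in whole.rows] == [key(r) for r in parts]

    def test_matched_seq_equals_slice_at_coordinates(self, rng):
        records, _ = _planted_records(rng)
        by_id = {r.id: r.sequence for r in records}
        table = scan_proteome(records, [builtin_catalog()["GC_CORE_STRICT"]])
        for row in table.rows:
            m = row.match
            assert m.matched == by_id[row.seq_id][m.start - 1 : m.end]
            assert 1 <= m.start <= m.end <= row.protein_length


class TestWriters:
    def test_tsv_round_trip(self, rng, tmp_path):
        records, _ = _planted_records(rng)
        table = scan_proteome(records, [builtin_catalog()["GC_CORE_STRICT"]])
        path = tmp_path / "scan.tsv"
        write_tsv(table, path)
        df = read_tsv(path)
        assert list(df.columns) == [
            "seq_id", "pattern", "start", "end", "matched_seq", "mismatches",
            "constrained_satisfied", "metal_offset", "metal_residue", "score",
            "protein_length",
        ]
        for row, (_, out) in zip(table.rows, df.iterrows()):
            assert (out["start"], out["end"]) == (row.match.start, row.match.end)
            assert out["score"] == pytest.approx(row.match.score, abs=5e-7)

    def test_empty_table_writes_header_only(self, tmp_path):
        from cyclasescan.scan import CandidateTable

        tsv, gff = tmp_path / "e.tsv", tmp_path / "e.gff3"
        write_tsv(CandidateTable(rows=[]), tsv)
        write_gff3(CandidateTable(rows=[]), gff)
        assert tsv.read_text().count("\n") == 1
        assert gff.read_text() == "##gff-version 3\n"

    def test_gff3_structure_and_coordinates(self, rng, tmp_path):
        records, coords = _planted_records(rng)
        table = scan_proteome(records, [builtin_catalog()["GC_CORE_STRICT"]])
        path = tmp_path / "scan.gff3"
        write_gff3(table, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        for line, (seq_id, start, end) in zip(lines[1:], coords):
            fields = line.split("\t")
            assert len(fields) == 9
            assert fields[0] == seq_id
            assert fields[2] == "polypeptide_motif"
            assert (int(fields[3]), int(fields[4])) == (start, end)
            assert 1 <= int(fields[3]) <= int(fields[4])
            assert "Name=GC_CORE_STRICT" in fields[8]

    def test_gff3_parses_with_gffutils(self, rng, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        records, coords = _planted_records(rng)
        table = scan_proteome(records, [builtin_catalog()["GC_CORE_STRICT"]])
        path = tmp_path / "scan.gff3"
        write_gff3(table, path)
        db = gffutils.create_db(str(path), ":memory:")
        feats = [(f.seqid, f.start, f.end) for f in db.all_features()]
        assert sorted(feats) == sorted(coords)
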