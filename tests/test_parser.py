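"""Entry picking, Molfile parsing, and the logged conversion pipeline."""

import bz2
import gzip

import pytest

from molstream import (MolstreamError, ParseError, canned_fixture,
                       canned_sdf, container_to_collection, convert_sdf,
                       parse_sdf_entry, pick_sdf_entries)
from molstream.parser import RawEntry


def _pick(text, **kw):
    return list(pick_sdf_entries(iter(text.splitlines(keepends=True)), **kw))


class TestPick:
    def test_single_entry(self):
        text, _ = canned_fixture("ethanol_heavy")
        entries = _pick(text + "$$$$\n")
        assert len(entries) == 1
        assert entries[0].entry_index == 1

    def test_three_entries_in_order(self):
        text = canned_sdf(["ethanol_heavy", "benzene_kekulized", "pyridine"])
        entries = _pick(text)
        assert [e.entry_index for e in entries] == [1, 2, 3]
        assert entries[2].lines[0] == "pyridine"

    def test_only_exact_delimiter_lines_split(self):
        text, _ = canned_fixture("ethanol_heavy")
        # put "$$" inside the comment line: must not split
        text = text.replace("\n\n", "\ncontains $$ but is no delimiter\n", 1)
        entries = _pick(text + "$$$$\n")
        assert len(entries) == 1

    def test_delimiter_with_trailing_whitespace_and_crlf(self):
        text, _ = canned_fixture("ethanol_heavy")
        crlf = text.replace("\n", "\r\n") + "$$$$   \r\n"
        entries = _pick(crlf)
        assert len(entries) == 1
        assert parse_sdf_entry(entries[0]).header.molecule_name == \
            "ethanol_heavy"

    def test_final_entry_without_delimiter_yields_warning(self):
        text, _ = canned_fixture("ethanol_heavy")
        events = []
        entries = _pick(text, on_event=lambda *a: events.append(a))
        assert len(entries) == 1
        assert events and events[0][2] == "pick"

    def test_empty_stream_yields_nothing(self):
        assert _pick("") == []

    def test_data_items_kept_opaque(self):
        text, _ = canned_fixture("ethanol_heavy")
        sdf = text + ">  <logP>\n1.23\n\n$$$$\n"
        [raw] = _pick(sdf)
        assert raw.lines[-1] == "M  END"
        assert raw.data_items_raw == ">  <logP>\n1.23\n\n"


def _raw(text, index=1):
    return RawEntry(lines=[ln.rstrip("\r\n")
                           for ln in text.splitlines()],
                    source_name="test", entry_index=index)


class TestParse:
    def test_ethanol_fields(self):
        text, _ = canned_fixture("ethanol_heavy")
        e = parse_sdf_entry(_raw(text))
        assert e.counts.n_atoms == 3 and e.counts.n_bonds == 2
        assert e.atoms[2].symbol == "O"
        assert [(b.first_atom, b.second_atom, b.bond_type)
                for b in e.bonds] == [(1, 2, 1), (2, 3, 1)]

    def test_benzene_bond_type_multiset(self):
        text, _ = canned_fixture("benzene_kekulized")
        e = parse_sdf_entry(_raw(text))
        assert e.counts.n_atoms == 6 and e.counts.n_bonds == 6
        types = sorted(b.bond_type for b in e.bonds)
        assert types == [1, 1, 1, 2, 2, 2]

    def test_all_canned_parse_to_expected(self, all_canned):
        for name, text, expected in all_canned:
            assert parse_sdf_entry(_raw(text)) == expected, name

    def test_truncated_atom_block(self):
        # counts claim 4 atoms but the block has only 3 lines (no bonds)
        text, _ = canned_fixture("ethanol_heavy")
        lines = text.splitlines()
        lines[3] = "  4  0  0  0  0  0  0  0  0  0999 V2000"
        del lines[7:9]  # drop the bond block
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw("\n".join(lines)))
        assert err.value.stage == "truncated block"
        assert err.value.row == 4

    def test_truncated_bond_block(self):
        text, _ = canned_fixture("ethanol_heavy")
        lines = text.splitlines()
        del lines[8]  # second of two declared bonds
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw("\n".join(lines)))
        assert err.value.stage == "truncated block"
        assert err.value.row == 2

    def test_version_tag_rejected(self):
        text, _ = canned_fixture("ethanol_heavy")
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw(text.replace("V2000", "V3000")))
        assert err.value.stage == "version"

    def test_garbled_counts_line(self):
        text, _ = canned_fixture("ethanol_heavy")
        lines = text.splitlines()
        lines[3] = " ab  2  0  0  0  0  0  0  0  0999 V2000"
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw("\n".join(lines)))
        assert err.value.stage == "counts"

    def test_garbled_atom_field_names_block_row_column(self):
        text, _ = canned_fixture("ethanol_heavy")
        lines = text.splitlines()
        lines[5] = lines[5][:36] + " X " + lines[5][39:]
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw("\n".join(lines)))
        assert err.value.stage == "atom" and err.value.row == 2
        assert "ccc" in str(err.value)

    def test_too_few_lines(self):
        with pytest.raises(ParseError) as err:
            parse_sdf_entry(_raw("only\nthree\nlines"))
        assert err.value.stage == "counts"

    def test_short_atom_line_whitespace_fallback_warns(self):
        text, _ = canned_fixture("ethanol_heavy")
        lines = text.splitlines()
        lines[5] = "    0.0000    0.0000    0.0000 C"  # ragged but parseable
        warnings = []
        e = parse_sdf_entry(_raw("\n".join(lines)),
                            on_warning=warnings.append)
        assert e.atoms[1].symbol == "C"
        assert any("fallback" in w for w in warnings)

    def test_properties_block_preserved_verbatim(self):
        text, expected = canned_fixture("charged_isotope")
        e = parse_sdf_entry(_raw(text))
        assert e.properties_raw == ["M  CHG  1   1   1", "M  ISO  1   1  15"]
        assert e == expected


class TestConvert:
    def test_all_valid_strict(self, five_sdf, tmp_path):
        out = tmp_path / "out.rbz"
        report = convert_sdf(five_sdf, out, log_path=tmp_path / "log.txt")
        assert (report.n_read, report.n_accepted, report.n_rejected) == \
            (5, 5, 0)
        names = [n for n, _ in container_to_collection(out)]
        assert len(names) == 5
        assert names[0].startswith("ethanol_heavy")

    def test_corrupt_entry_rejected_and_logged(self, tmp_path):
        blocks = [canned_fixture(n)[0] for n in
                  ["ethanol_heavy", "benzene_kekulized", "pyridine",
                   "methane_full_H", "cyclohexane"]]
        # corrupt entry 3 with an out-of-range bond index
        blocks[2] = blocks[2].replace("  1  2  1  0  0  0  0",
                                      "  1  9  1  0  0  0  0", 1)
        sdf = tmp_path / "c.sdf"
        sdf.write_text("$$$$\n".join(blocks) + "$$$$\n", encoding="utf-8")
        log = tmp_path / "log.txt"
        report = convert_sdf(sdf, tmp_path / "out.rbz", log_path=log)
        assert (report.n_accepted, report.n_rejected) == (4, 1)
        assert report.errors[0][0] == 3
        lines = [ln for ln in log.read_text().splitlines()
                 if "\tERROR\t" in ln]
        assert len(lines) == 1 and "\t3\t" in lines[0]

    def test_empty_sdf_gives_empty_valid_container(self, tmp_path):
        sdf = tmp_path / "empty.sdf"
        sdf.write_text("", encoding="utf-8")
        out = tmp_path / "out.rbz"
        report = convert_sdf(sdf, out)
        assert (report.n_read, report.n_accepted, report.n_rejected) == \
            (0, 0, 0)
        assert container_to_collection(out) == []

    def test_lenient_keeps_plausibility_warnings(self, tmp_path):
        text, _ = canned_fixture("ethanol_heavy")
        odd = text.replace(" O  ", " Zz ")
        sdf = tmp_path / "odd.sdf"
        sdf.write_text(odd + "$$$$\n", encoding="utf-8")
        strict = convert_sdf(sdf, tmp_path / "s.rbz")
        lenient = convert_sdf(sdf, tmp_path / "l.rbz", strict=False)
        assert strict.n_rejected == 1
        assert lenient.n_accepted == 1

    def test_unreadable_input_is_io_error(self, tmp_path):
        with pytest.raises((MolstreamError, OSError)):
            convert_sdf(tmp_path / "missing.sdf", tmp_path / "out.rbz")

    def test_no_partial_container_on_failure(self, tmp_path):
        sdf = tmp_path / "t.sdf"
        sdf.write_text(canned_sdf(["ethanol_heavy"]), encoding="utf-8")
        out = tmp_path / "nodir" / "out.rbz"
        with pytest.raises((MolstreamError, OSError)):
            convert_sdf(sdf, out)
        assert not out.exists()

    @pytest.mark.parametrize("compress", [gzip.compress, bz2.compress])
    def test_compressed_sdf_input_sniffed(self, tmp_path, compress):
        data = canned_sdf(["ethanol_heavy", "pyridine"]).encode("latin-1")
        sdf = tmp_path / "in.sdf.x"
        sdf.write_bytes(compress(data))
        report = convert_sdf(sdf, tmp_path / "out.rbz")
        assert report.n_accepted == 2

    def test_deterministic_container_bytes(self, five_sdf, tmp_path):
        a, b = tmp_path / "a.rbz", tmp_path / "b.rbz"
        convert_sdf(five_sdf, a)
        convert_sdf(five_sdf, b)
        assert a.read_bytes() == b.read_bytes()

    def test_keep_data_items(self, tmp_path):
        text, _ = canned_fixture("ethanol_heavy")
        sdf = tmp_path / "d.sdf"
        sdf.write_text(text + ">  <logP>\n1.23\n\n$$$$\n", encoding="utf-8")
        out = tmp_path / "out.rbz"
        convert_sdf(sdf, out, keep_data_items=True)
        from molstream import read_records
        [rec] = list(read_records(out))
        assert rec.data_items_raw == ">  <logP>\n1.23\n\n"
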