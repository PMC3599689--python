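"""Collection statistics, deterministic reports, and filter semantics."""

import pytest

from molstream import (CollectionSummary, FilterSpec, FilterSpecError,
                       atom_count_in, bond_count_in, canned_fixture,
                       collection_to_container,
                       contains_element, container_to_collection,
                       filter_collection, format_summary_report,
                       has_bond_type, lacks_element, merge_summaries,
                       name_matches, parse_clause, passes_check,
                       summarize_collection, summary_report)


@pytest.fixture
def ethanol_benzene_container(tmp_path):
    p = tmp_path / "eb.rbz"
    collection_to_container(
        [("ethanol", canned_fixture("ethanol_heavy")[1]),
         ("benzene", canned_fixture("benzene_kekulized")[1])], p)
    return p


class TestSummary:
    def test_counts_by_hand(self, ethanol_benzene_container):
        s = summarize_collection(ethanol_benzene_container)
        assert s.n_entries == 2
        assert s.element_frequency == {"C": 8, "O": 1}
        assert s.atom_count_stats.min == 3
        assert s.atom_count_stats.max == 6
        assert s.bond_type_frequency == {1: 5, 2: 3}
        assert s.n_entries_with_violations == 0

    def test_empty_container(self, tmp_path):
        p = tmp_path / "e.rbz"
        collection_to_container([], p)
        s = summarize_collection(p)
        assert s.n_entries == 0
        assert s.element_frequency == {}
        assert s.atom_count_stats is None

    def test_frequency_invariants_on_generated_collection(self, tmp_path):
        from molstream import GenSpec, generate_sdf, convert_sdf
        sdf, out = tmp_path / "g.sdf", tmp_path / "g.rbz"
        manifest = generate_sdf(GenSpec(n_molecules=100, seed=3), sdf)
        convert_sdf(sdf, out)
        s = summarize_collection(out)
        assert sum(s.element_frequency.values()) == \
            sum(r.n_atoms for r in manifest)
        assert sum(s.bond_type_frequency.values()) == \
            sum(r.n_bonds for r in manifest)
        # per-element totals match the generator's bookkeeping
        totals: dict[str, int] = {}
        for r in manifest:
            for sym, c in r.element_counts.items():
                totals[sym] = totals.get(sym, 0) + c
        assert s.element_frequency == totals

    def test_additivity_under_concatenation(self, tmp_path):
        from molstream import GenSpec, generate_sdf, convert_sdf
        sdf_a, sdf_b = tmp_path / "a.sdf", tmp_path / "b.sdf"
        generate_sdf(GenSpec(n_molecules=30, seed=1), sdf_a)
        generate_sdf(GenSpec(n_molecules=20, seed=2), sdf_b)
        ab = tmp_path / "ab.sdf"
        ab.write_bytes(sdf_a.read_bytes() + sdf_b.read_bytes())
        ca, cb, cab = (tmp_path / n for n in ("a.rbz", "b.rbz", "ab.rbz"))
        convert_sdf(sdf_a, ca)
        convert_sdf(sdf_b, cb)
        convert_sdf(ab, cab)
        merged = merge_summaries(summarize_collection(ca),
                                 summarize_collection(cb))
        whole = summarize_collection(cab)
        assert merged.n_entries == whole.n_entries
        assert merged.element_frequency == whole.element_frequency
        assert merged.bond_type_frequency == whole.bond_type_frequency
        assert [r[1:] for r in merged.per_entry_index] == \
            [r[1:] for r in whole.per_entry_index]


class TestReport:
    def test_byte_deterministic(self, ethanol_benzene_container, tmp_path):
        s1 = summarize_collection(ethanol_benzene_container)
        s2 = summarize_collection(ethanol_benzene_container)
        p1, p2 = tmp_path / "r1.txt", tmp_path / "r2.txt"
        summary_report(s1, p1)
        summary_report(s2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tie_break_count_desc_then_symbol(self):
        s = CollectionSummary(n_entries=1,
                              element_frequency={"O": 4, "C": 4, "N": 7})
        text = format_summary_report(s)
        section = text.split("Element frequencies")[1]
        rows = [ln.split()[0] for ln in section.splitlines()
                if ln and ln[0].isalpha() and " " in ln]
        assert rows[:3] == ["N", "C", "O"]

    def test_empty_summary_report(self):
        text = format_summary_report(CollectionSummary())
        assert "entries:                 0" in text
        assert "(no entries)" in text


class TestFilter:
    def test_contains_nitrogen_selects_pyridine(self, five_container,
                                                tmp_path):
        spec = FilterSpec((contains_element("N"),))
        acc, rej = tmp_path / "a.rbz", tmp_path / "r.rbz"
        n_in, n_acc, n_rej = filter_collection(five_container, spec, acc,
                                               rej)
        assert (n_in, n_acc, n_rej) == (5, 1, 4)
        [(name, entry)] = container_to_collection(acc)
        assert name.startswith("pyridine")

    def test_vacuous_range_accepts_everything(self, five_container,
                                              tmp_path):
        spec = FilterSpec((atom_count_in(0),))
        n_in, n_acc, n_rej = filter_collection(
            five_container, spec, tmp_path / "a.rbz", tmp_path / "r.rbz")
        assert (n_acc, n_rej) == (5, 0)
        assert container_to_collection(tmp_path / "r.rbz") == []

    @pytest.mark.parametrize("clause", [
        atom_count_in(3, 6), bond_count_in(0, 4), contains_element("C"),
        lacks_element("N"), name_matches("^benz"), has_bond_type(2),
        passes_check(),
    ])
    def test_partition_law(self, five_container, tmp_path, clause):
        spec = FilterSpec((clause,))
        filter_collection(five_container, spec, tmp_path / "a.rbz")
        filter_collection(five_container, spec.negated(),
                          tmp_path / "na.rbz")
        acc = [n for n, _ in container_to_collection(tmp_path / "a.rbz")]
        nacc = [n for n, _ in container_to_collection(tmp_path / "na.rbz")]
        whole = [n for n, _ in container_to_collection(five_container)]
        assert not (set(acc) & set(nacc))
        assert sorted(acc + nacc) == sorted(whole)
        # order preserved within each side
        assert acc == [n for n in whole if n in set(acc)]
        assert nacc == [n for n in whole if n in set(nacc)]

    def test_reject_path_optional_but_counted(self, five_container,
                                              tmp_path):
        spec = FilterSpec((contains_element("O"),))
        n_in, n_acc, n_rej = filter_collection(five_container, spec,
                                               tmp_path / "a.rbz")
        assert n_in == n_acc + n_rej == 5

    def test_invalid_regex_fails_before_io(self, tmp_path):
        with pytest.raises(FilterSpecError):
            name_matches("([unclosed")

    def test_empty_spec_rejected(self):
        with pytest.raises(FilterSpecError):
            FilterSpec(())

    def test_combinator_any(self, five_container, tmp_path):
        spec = FilterSpec((contains_element("N"), contains_element("O")),
                          combinator="any")
        _, n_acc, _ = filter_collection(five_container, spec,
                                        tmp_path / "a.rbz")
        assert n_acc == 2  # pyridine and ethanol

    @pytest.mark.parametrize("text,expected_kind", [
        ("contains-element=N", "contains_element"),
        ("atom-count=2:9", "atom_count_in"),
        ("bond-count=0:*", "bond_count_in"),
        ("name-matches=^gen_", "name_matches"),
        ("has-bond-type=2", "has_bond_type"),
        ("passes-check", "passes_check"),
    ])
    def test_clause_parsing(self, text, expected_kind):
        assert parse_clause(text).kind == expected_kind

    def test_unknown_clause_rejected(self):
        with pytest.raises(FilterSpecError):
            parse_clause("molecular-weight=300")
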