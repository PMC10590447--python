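"""De-replication: scoring, NC filtering, pair removal, reassignment.

The randomized checks compare against an independent plain-loop oracle
that re-applies the three rules (score filter, near-identical pair
removal, largest-score-drop reassignment) on dict/set data structures.
"""

import numpy as np
import pandas as pd
import pytest

from aaebin.clustering import BinSet
from aaebin.dereplication import (
    QualityReport,
    ScoredBin,
    dereplicate,
    filter_nc,
    find_near_identical_pairs,
    parse_quality_report,
    score_bins,
)
from aaebin.synthetic import GroundTruthScorer


def oracle_dereplicate(
    bin_sets, scorer, lengths, min_comp=0.9, max_cont=0.05, thr=0.75
):
    """Independent reference: plain loops, recomputing pairs each round."""
    bins = {}
    for bs in bin_sets:
        bins.update({k: frozenset(v) for k, v in bs.bins.items()})

    def score(name, contigs):
        c, x = scorer.score_bin(name, contigs)
        return c - 5.0 * x

    def bp(contigs):
        return sum(lengths[c] for c in contigs)

    alive = {}
    for name, contigs in bins.items():
        c, x = scorer.score_bin(name, contigs)
        if c > min_comp and x < max_cont:
            alive[name] = contigs

    while True:
        pairs = []
        names = sorted(alive)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared = alive[a] & alive[b]
                if not shared:
                    continue
                smaller = min(bp(alive[a]), bp(alive[b]))
                if smaller == 0:
                    continue
                ov = bp(shared) / smaller
                if ov >= thr:
                    pairs.append((ov, a, b))
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        removed = set()
        for ov, a, b in pairs:
            if a in removed or b in removed:
                continue
            sa, sb = score(a, alive[a]), score(b, alive[b])
            if sa != sb:
                loser = a if sa < sb else b
            elif bp(alive[a]) != bp(alive[b]):
                loser = a if bp(alive[a]) < bp(alive[b]) else b
            else:
                loser = max(a, b)
            removed.add(loser)
        for r in removed:
            del alive[r]

    owners_of = {}
    for name, contigs in alive.items():
        for c in contigs:
            owners_of.setdefault(c, []).append(name)
    for contig in sorted(c for c, o in owners_of.items() if len(o) > 1):
        owners = sorted(
            n for n in owners_of[contig] if n in alive and contig in alive[n]
        )
        if len(owners) < 2:
            continue
        drops = {
            n: score(n, alive[n]) - score(n, alive[n] - {contig}) for n in owners
        }
        winner = min(owners, key=lambda n: (-drops[n], -score(n, alive[n]), n))
        for n in owners:
            if n == winner:
                continue
            rest = alive[n] - {contig}
            if rest:
                alive[n] = rest
            else:
                del alive[n]
    return {k: set(v) for k, v in alive.items()}


class StaticScorer:
    """Content-aware scorer backed by an explicit lookup table."""

    def __init__(self, table):
        self.table = table  # (name, frozenset) -> (comp, cont)

    def score_bin(self, name, contigs):
        return self.table[(name, frozenset(contigs))]


class TestScoreBins:
    @pytest.mark.parametrize(
        "comp,cont,expected",
        [(1.0, 0.0, 1.0), (0.9, 0.05, 0.65), (0.9, 0.2, -0.1)],
    )
    def test_score_formula(self, comp, cont, expected):
        report = QualityReport(entries={"b": (comp, cont)})
        [scored] = score_bins(
            BinSet(bins={"b": {"S1C1"}}), report, {"S1C1": 100}
        )
        assert scored.score == pytest.approx(expected)
        assert scored.total_bp == 100

    def test_missing_bin_is_an_error(self):
        report = QualityReport(entries={})
        with pytest.raises(KeyError, match="b"):
            score_bins(BinSet(bins={"b": {"S1C1"}}), report, {"S1C1": 100})


class TestFilterNC:
    @pytest.mark.parametrize(
        "comp,cont,kept",
        [
            (0.95, 0.01, True),
            (0.90, 0.01, False),  # strict > on completeness
            (0.99, 0.05, False),  # strict < on contamination
            (0.91, 0.049, True),
        ],
    )
    def test_strict_boundaries(self, comp, cont, kept):
        b = ScoredBin("b", frozenset({"S1C1"}), 100, comp, cont)
        assert (len(filter_nc([b])) == 1) is kept


class TestNearIdenticalPairs:
    def _bin(self, name, contigs, bp_each=100):
        return ScoredBin(
            name, frozenset(contigs), bp_each * len(contigs), 1.0, 0.0
        )

    def test_identical_and_disjoint(self):
        lengths = {f"S1C{i}": 100 for i in range(6)}
        a = self._bin("a", {"S1C1", "S1C2"})
        b = self._bin("b", {"S1C1", "S1C2"})
        c = self._bin("c", {"S1C4", "S1C5"})
        pairs = find_near_identical_pairs([a, b, c], lengths)
        assert [(p[0].name, p[1].name, p[2]) for p in pairs] == [("a", "b", 1.0)]

    def test_overlap_of_smaller_bin(self):
        # small bin 100 bp shares its 80 bp contig with a larger bin
        lengths = {"S1C1": 80, "S1C2": 20, "S1C3": 500}
        small = ScoredBin("small", frozenset({"S1C1", "S1C2"}), 100, 1.0, 0.0)
        large = ScoredBin("large", frozenset({"S1C1", "S1C3"}), 580, 1.0, 0.0)
        pairs = find_near_identical_pairs([small, large], lengths)
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.8)
        none = find_near_identical_pairs([small, large], lengths, 0.81)
        assert none == []


class TestDereplicate:
    def test_identical_bins_keep_higher_score(self):
        lengths = {"S1C1": 100, "S1C2": 100}
        contigs = {"S1C1", "S1C2"}
        report = QualityReport(
            entries={"a": (0.95, 0.01), "b": (0.92, 0.024)}  # scores 0.90, 0.80
        )
        result = dereplicate(
            [BinSet(bins={"a": set(contigs)}), BinSet(bins={"b": set(contigs)})],
            report,
            lengths,
        )
        assert set(result.bins) == {"a"}

    def test_largest_score_drop_wins_contig(self):
        # P and Q share one contig but are not near-identical; removing the
        # contig costs P 0.30 and Q 0.05
        lengths = {"S1C1": 100, "S1C2": 100, "S1C3": 100, "S1C4": 100, "S1C5": 100}
        p_full = frozenset({"S1C1", "S1C2", "S1C5"})
        q_full = frozenset({"S1C3", "S1C4", "S1C5"})
        table = {
            ("P", p_full): (0.95, 0.0),
            ("P", p_full - {"S1C5"}): (0.65, 0.0),
            ("Q", q_full): (0.96, 0.0),
            ("Q", q_full - {"S1C5"}): (0.91, 0.0),
        }
        result = dereplicate(
            [BinSet(bins={"P": set(p_full)}), BinSet(bins={"Q": set(q_full)})],
            StaticScorer(table),
            lengths,
        )
        assert "S1C5" in result.bins["P"]
        assert "S1C5" not in result.bins["Q"]

    def test_duplicate_bin_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate bin name"):
            dereplicate(
                [BinSet(bins={"a": {"S1C1"}}), BinSet(bins={"a": {"S1C1"}})],
                QualityReport(entries={"a": (1.0, 0.0)}),
                {"S1C1": 100},
            )

    def test_never_gains_bins_and_keeps_only_inputs(self, tiny_meta):
        scorer = GroundTruthScorer(tiny_meta.truth)
        genome_of = tiny_meta.genome_of
        bins = {}
        for g in sorted(set(genome_of.values())):
            bins[f"z{g}"] = {c for c, gg in genome_of.items() if gg == g}
            bins[f"y{g}"] = set(bins[f"z{g}"])
        result = dereplicate(
            [
                BinSet(bins={k: v for k, v in bins.items() if k.startswith("z")}),
                BinSet(bins={k: v for k, v in bins.items() if k.startswith("y")}),
            ],
            scorer,
            tiny_meta.contig_lengths,
        )
        assert set(result.bins) <= set(bins)
        assert len(result.bins) <= len(bins)

    def test_order_invariance(self, tiny_meta):
        scorer = GroundTruthScorer(tiny_meta.truth)
        genome_of = tiny_meta.genome_of
        z = {}
        y = {}
        for g in sorted(set(genome_of.values())):
            members = {c for c, gg in genome_of.items() if gg == g}
            z[f"z{g}"] = members
            y[f"y{g}"] = set(members)
        ab = dereplicate(
            [BinSet(bins=z), BinSet(bins=y)], scorer, tiny_meta.contig_lengths
        )
        ba = dereplicate(
            [BinSet(bins=y), BinSet(bins=z)], scorer, tiny_meta.contig_lengths
        )
        assert ab.bins == ba.bins

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_small_instances(self, seed):
        """Randomized instances of <= 4 bins / <= 12 contigs agree with the
        plain-loop oracle, and the result never duplicates a contig."""
        rng = np.random.default_rng(seed)
        n_contigs = int(rng.integers(6, 13))
        contigs = [f"S1C{i}" for i in range(n_contigs)]
        lengths = {c: int(rng.integers(50, 500)) for c in contigs}
        genomes = [f"G{i}" for i in range(int(rng.integers(2, 4)))]
        genome_of = {c: genomes[int(rng.integers(0, len(genomes)))] for c in contigs}
        truth = pd.DataFrame(
            {
                "contig": contigs,
                "genome": [genome_of[c] for c in contigs],
                "covered_bp": [lengths[c] for c in contigs],
            }
        )
        scorer = GroundTruthScorer(truth)
        n_bins = int(rng.integers(2, 5))
        sets = []
        for b in range(n_bins):
            g = genomes[int(rng.integers(0, len(genomes)))]
            members = {c for c in contigs if genome_of[c] == g}
            # perturb: sometimes drop one member, sometimes add a stray
            members = set(rng.permutation(sorted(members))[: max(1, len(members))])
            if rng.random() < 0.4 and len(members) > 1:
                members.discard(sorted(members)[0])
            if rng.random() < 0.4:
                members.add(contigs[int(rng.integers(0, n_contigs))])
            sets.append(BinSet(bins={f"bin{b}": members}))
        result = dereplicate(sets, scorer, lengths)
        expected = oracle_dereplicate(sets, scorer, lengths)
        assert result.bins == expected
        seen = set()
        for members in result.bins.values():
            assert not (seen & members)
            seen |= members

    def test_reproducible(self, tiny_meta):
        scorer = GroundTruthScorer(tiny_meta.truth)
        genome_of = tiny_meta.genome_of
        bins = {
            f"z{g}": {c for c, gg in genome_of.items() if gg == g}
            for g in set(genome_of.values())
        }
        runs = [
            dereplicate([BinSet(bins=dict(bins))], scorer, tiny_meta.contig_lengths)
            for _ in range(2)
        ]
        assert runs[0].bins == runs[1].bins


class TestParseQualityReport:
    def _write(self, path, rows, header="Name\tCompleteness\tContamination"):
        path.write_text(header + "\n" + "\n".join(rows) + "\n")

    def test_percent_scale(self, tmp_path):
        path = tmp_path / "q.tsv"
        self._write(path, ["bin1\t95.2\t1.3"])
        report = parse_quality_report(path)
        assert report.entries["bin1"] == pytest.approx((0.952, 0.013))

    def test_fraction_scale(self, tmp_path):
        path = tmp_path / "q.tsv"
        self._write(path, ["bin1\t0.95\t0.01"])
        assert parse_quality_report(path).entries["bin1"] == (0.95, 0.01)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "q.tsv"
        self._write(path, ["bin1\t0.95"], header="Name\tCompleteness")
        with pytest.raises(ValueError, match="contamination"):
            parse_quality_report(path)
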