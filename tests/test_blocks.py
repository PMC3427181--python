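"""Conserved-block selection: column classification and block rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modevoprof import (
    BlockParams,
    ProteinAlignment,
    classify_columns,
    filter_alignment,
    relaxed_params,
    select_blocks,
    strict_params,
)
from modevoprof.blocks import CONSERVED, HIGHLY_CONSERVED, NONCONSERVED


def aln_from_columns(cols):
    """Build an alignment from a list of column strings."""
    n = len(cols[0])
    rows = tuple("".join(col[i] for col in cols) for i in range(n))
    ids = tuple(f"s{i}" for i in range(n))
    return ProteinAlignment(ids, rows)


class TestClassify:
    def test_identical_rows_all_highly_conserved(self):
        aln = ProteinAlignment(
            tuple(f"s{i}" for i in range(10)), tuple(["MKVA"] * 10)
        )
        st_ = classify_columns(aln, relaxed_params(10))
        assert (st_ == HIGHLY_CONSERVED).all()

    def test_majority_gap_column_nonconserved_under_with_half(self):
        col = "AAAA" + "-" * 6  # 6/10 gaps
        aln = aln_from_columns([col])
        params = BlockParams(2, 2, gap_policy="with_half")
        assert classify_columns(aln, params)[0] == NONCONSERVED

    def test_any_gap_nonconserved_under_none_policy(self):
        aln = aln_from_columns(["AAAAAAAAA-"])
        params = BlockParams(2, 2, gap_policy="none")
        assert classify_columns(aln, params)[0] == NONCONSERVED

    def test_gaps_ignored_under_all_policy(self):
        aln = aln_from_columns(["AAAAAA----"])
        params = BlockParams(6, 6, gap_policy="all")
        assert classify_columns(aln, params)[0] == HIGHLY_CONSERVED

    def test_hand_counted_majority_column(self):
        # (A x6, S x4), n=10: count 6 >= min_conserved 6 but < flank 9
        aln = aln_from_columns(["AAAAAASSSS"])
        params = BlockParams(6, 9, gap_policy="all")
        assert classify_columns(aln, params)[0] == CONSERVED

    def test_x_never_counts_as_residue(self):
        aln = aln_from_columns(["AXXXXXXXXX"])
        params = BlockParams(2, 2, gap_policy="all")
        assert classify_columns(aln, params)[0] == NONCONSERVED


def oracle_select(statuses, max_contig, min_block):
    """Straightforward independent evaluation of the three block rules."""
    C = len(statuses)
    keep = [True] * C
    run = []
    for i in range(C + 1):
        if i < C and statuses[i] == NONCONSERVED:
            run.append(i)
        else:
            if len(run) > max_contig:
                for j in run:
                    keep[j] = False
            run = []
    blocks = []
    i = 0
    while i < C:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < C and keep[j]:
            j += 1
        seg = list(range(i, j))
        while seg and statuses[seg[0]] != HIGHLY_CONSERVED:
            seg.pop(0)
        while seg and statuses[seg[-1]] != HIGHLY_CONSERVED:
            seg.pop()
        if len(seg) >= min_block:
            blocks.append((seg[0] + 1, seg[-1] + 1))
        i = j
    return blocks


class TestSelectBlocks:
    def test_all_highly_conserved_single_block(self):
        params = BlockParams(2, 2, min_block_len=5)
        sel = select_blocks(np.full(30, HIGHLY_CONSERVED), params)
        assert sel.blocks == ((1, 30),)
        assert sel.kept_columns == tuple(range(1, 31))

    def test_all_nonconserved_empty(self):
        params = BlockParams(2, 2)
        sel = select_blocks(np.full(30, NONCONSERVED), params)
        assert sel.blocks == ()
        assert sel.kept_columns == ()

    def test_sixty_column_pattern_matches_rule_oracle(self):
        # one 12-column nonconserved run inside an otherwise conserved
        # alignment; max_contig 8 excises it, splitting two blocks
        statuses = np.full(60, HIGHLY_CONSERVED)
        statuses[20:32] = NONCONSERVED
        statuses[5] = CONSERVED
        statuses[50] = NONCONSERVED  # short run, survives inside a block
        params = BlockParams(2, 2, max_contig_nonconserved=8, min_block_len=5)
        sel = select_blocks(statuses, params)
        assert len(sel.blocks) == 2
        assert list(sel.blocks) == oracle_select(statuses, 8, 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 2), min_size=1, max_size=80),
        st.integers(1, 10),
        st.integers(1, 12),
    )
    def test_matches_rule_oracle_randomized(self, statuses, max_contig, min_block):
        params = BlockParams(2, 2, max_contig_nonconserved=max_contig,
                             min_block_len=min_block)
        sel = select_blocks(np.array(statuses), params)
        assert list(sel.blocks) == oracle_select(statuses, max_contig, min_block)
        # kept_columns is exactly the union of blocks
        union = [c for (s, e) in sel.blocks for c in range(s, e + 1)]
        assert list(sel.kept_columns) == union


def random_alignment(rng, n=10, C=60, alphabet="ADKS-"):
    probs = [0.4, 0.25, 0.15, 0.1, 0.1]
    rows = rng.choice(list(alphabet), size=(n, C), p=probs)
    return ProteinAlignment(
        tuple(f"s{i}" for i in range(n)),
        tuple("".join(r) for r in rows),
    )


class TestProperties:
    def test_raising_conservation_threshold_never_keeps_more(self, rng):
        aln = random_alignment(rng)
        kept = []
        for mc in range(1, 9):
            params = BlockParams(mc, max(mc, 8), gap_policy="with_half")
            _, sel = filter_alignment(aln, params=params)
            kept.append(len(sel.kept_columns))
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_idempotence_on_selected_subalignment(self, rng):
        for _ in range(10):
            aln = random_alignment(rng)
            params = relaxed_params(aln.n_seqs)
            sub, sel = filter_alignment(aln, params=params)
            if sub is None:
                continue
            sub2, sel2 = filter_alignment(sub, params=params)
            assert sel2.kept_columns == tuple(range(1, sub.n_cols + 1))

    def test_permissive_params_keep_everything(self, rng):
        aln = random_alignment(rng)
        params = BlockParams(
            1, 1, max_contig_nonconserved=aln.n_cols, min_block_len=1,
            gap_policy="all",
        )
        _, sel = filter_alignment(aln, params=params)
        assert sel.kept_columns == tuple(range(1, aln.n_cols + 1))

    def test_presets_are_ordered(self):
        rel, stri = relaxed_params(20), strict_params(20)
        assert stri.min_seqs_flank >= rel.min_seqs_flank
        assert stri.min_block_len >= rel.min_block_len
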