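import io

import pytest
from hypothesis import given, settings, strategies as st

from suppsignal import (
    Paragraph,
    ProductEntry,
    apply_tuple_filter,
    load_effects,
    load_hits,
    load_products,
    match_effects,
    match_products,
    search_paragraph,
    tokenize,
    write_hits,
)
from suppsignal.synthetic import SimConfig, generate_corpus, generate_lexicons
from suppsignal.matcher import search_corpus

from conftest import EXAMPLE_I_TEXT
from oracles import brute_force_hits, hit_key_set


class TestTokenize:
    def test_hyphen_and_apostrophe_stay_internal(self):
        assert [t.text for t in tokenize("No-xplode werkt!")] == [
            "No-xplode", "werkt", "!",
        ]
        assert [t.text for t in tokenize("'s nachts wakker")] == [
            "'s", "nachts", "wakker",
        ]

    def test_empty(self):
        assert tokenize("") == []

    def test_offsets_slice_back_to_token_text(self):
        text = "zo'n 10% van mijn rpm erbij"
        for token in tokenize(text):
            assert text[token.start : token.end] == token.text

    @given(st.text(max_size=80))
    @settings(derandomize=True, max_examples=300)
    def test_reconstruction(self, text):
        tokens = tokenize(text)
        # tokens are non-overlapping, in order, and cover all non-space chars
        pos = 0
        rebuilt = []
        for token in tokens:
            assert token.start >= pos
            assert text[token.start : token.end] == token.text
            rebuilt.append(text[pos : token.start])
            rebuilt.append(token.text)
            pos = token.end
        rebuilt.append(text[pos:])
        assert "".join(rebuilt) == text


class TestMatchProducts:
    def test_lowercase_variant_matches_case_insensitively(self):
        products = [ProductEntry("RPM", "product", frozenset({"rpm"}))]
        tokens = tokenize("zo'n 10% van mijn rpm erbij")
        matches = match_products(tokens, "p#0", products)
        assert len(matches) == 1
        assert matches[0].entry.canonical == "RPM"
        assert matches[0].matched_variant == "rpm"

    def test_no_variant_no_match(self):
        products = [ProductEntry("RPM", "product")]
        assert match_products(tokenize("niks te zien hier"), "p#0", products) == []

    def test_longest_variant_wins_and_suppresses_overlap(self):
        products = [
            ProductEntry("Super Pomp", "product", frozenset({"super pomp"})),
            ProductEntry("Pomp", "product", frozenset({"pomp"})),
        ]
        tokens = tokenize("die super pomp werkt")
        matches = match_products(tokens, "p#0", products)
        assert [m.entry.canonical for m in matches] == ["Super Pomp"]

    def test_planted_variants_found_at_planted_spans(self):
        products = [
            ProductEntry("Alfax", "product"),
            ProductEntry("Betarol", "product", frozenset({"beta"})),
        ]
        text = "eerst Alfax geprobeerd daarna beta genomen en weer alfax"
        tokens = tokenize(text)
        matches = match_products(tokens, "p#0", products)
        got = {(m.entry.canonical, text[m.span[0] : m.span[1]]) for m in matches}
        assert got == {("Alfax", "Alfax"), ("Betarol", "beta"), ("Alfax", "alfax")}
        assert len(matches) == 3


class TestMatchEffects:
    def _lexicon(self, vocab, rules):
        return load_effects(io.StringIO(vocab), io.StringIO(rules))

    def test_adjective_plus_vague_noun_rule(self):
        lex = self._lexicon(
            "misselijkmakend\tADJ\teffect_adj\t0\t-\neffect\tNOUN\tvague_noun\t0\t-\n",
            "r1\tsem:effect_adj+lit:effect\t0\tunspecified\n",
        )
        text = "echt een misselijkmakend effect gehad"
        matches = match_effects(tokenize(text), "p#0", lex, text=text)
        assert len(matches) == 1
        assert matches[0].matched_text == "misselijkmakend effect"
        assert matches[0].source == "rule:r1"

    def test_sentiment_plus_verb_rule(self):
        lex = self._lexicon(
            "dramatisch\tADV\tsentiment\t0\t-\nafgevallen\tVERB\tverb_effect\t0\t-\n",
            "r1\tsem:sentiment+pos:VERB\t0\tbody fat\n",
        )
        text = "ben dramatisch afgevallen deze maand"
        matches = match_effects(tokenize(text), "p#0", lex, text=text)
        assert [m.matched_text for m in matches] == ["dramatisch afgevallen"]
        assert matches[0].type_label == "body fat"

    def test_gap_allows_intervening_token(self):
        lex = self._lexicon(
            "lever\tNOUN\tbody_part\t0\t-\naantasten\tVERB\tverb_effect\t0\t-\n",
            "r1\tsem:body_part+sem:verb_effect\t1\tmaag, lever en darmen\n",
        )
        for text in ("lever aantasten", "lever kan aantasten"):
            matches = match_effects(tokenize(text), "p#0", lex, text=text)
            assert [m.matched_text for m in matches] == [text]
        wide = "lever kan het aantasten"
        assert match_effects(tokenize(wide), "p#0", lex, text=wide) == []

    def test_same_sleep_label_via_vocab_and_rule(self):
        lex = self._lexicon(
            "slapeloosheid\tNOUN\teffect_noun\t1\tsleep\n"
            "slapen\tVERB\tverb_effect\t0\t-\n"
            "niet\tADV\tsentiment\t0\t-\n",
            "r1\tlit:niet+lit:slapen\t0\tsleep\n",
        )
        t1 = "heb last van slapeloosheid gehad"
        t2 = "kan niet slapen de laatste tijd"
        m1 = match_effects(tokenize(t1), "a#0", lex, text=t1)
        m2 = match_effects(tokenize(t2), "b#0", lex, text=t2)
        assert {m.type_label for m in m1} == {"sleep"}
        assert {m.type_label for m in m2} == {"sleep"}

    def test_standalone_bigram_requires_adjacency(self):
        lex = self._lexicon(
            "vocht vasthoud\tNOUN\teffect_noun\t1\tbelly\n", ""
        )
        hit_text = "ik merk dat ik vocht vasthoud nu"
        miss_text = "ik merk vocht , vasthoud niet"
        assert len(match_effects(tokenize(hit_text), "p", lex, text=hit_text)) == 1
        assert match_effects(tokenize(miss_text), "p", lex, text=miss_text) == []

    def test_negation_is_not_handled(self):
        # negation blindness is a documented property, asserted here
        lex = self._lexicon("diarree\tNOUN\teffect_noun\t1\tmaag, lever en darmen\n", "")
        text = "geen last van diarree gehad"
        matches = match_effects(tokenize(text), "p#0", lex, text=text)
        assert [m.matched_text for m in matches] == ["diarree"]


class TestTupleFilter:
    def _effects(self, n):
        lex = load_effects(
            io.StringIO("pijn\tNOUN\teffect_noun\t1\tharm\n"), io.StringIO("")
        )
        text = " ".join(["pijn"] * n) if n else "niks"
        return match_effects(tokenize(text), "p#0", lex, text=text)

    def test_no_effects_no_hits(self):
        products = [ProductEntry("RPM", "product")]
        pm = match_products(tokenize("rpm hier"), "p#0", products)
        assert apply_tuple_filter("p#0", pm, []) == []

    def test_no_products_no_hits(self):
        assert apply_tuple_filter("p#0", [], self._effects(2)) == []

    @pytest.mark.parametrize("n_products,n_effects", [(1, 1), (2, 3), (3, 2)])
    def test_cross_product_size(self, n_products, n_effects):
        names = ["Alfax", "Betarol", "Gammon"][:n_products]
        products = [ProductEntry(n, "product") for n in names]
        text = " ".join(names)
        pm = match_products(tokenize(text), "p#0", products)
        effects = self._effects(n_effects)
        hits = apply_tuple_filter("p#0", pm, effects)
        assert len(hits) == n_products * n_effects
        assert {h.product_canonical for h in hits} == set(names)

    def test_duplicate_product_mentions_collapse(self):
        products = [ProductEntry("Alfax", "product")]
        text = "alfax en nog eens Alfax"
        pm = match_products(tokenize(text), "p#0", products)
        assert len(pm) == 2
        hits = apply_tuple_filter("p#0", pm, self._effects(1))
        assert len(hits) == 1


class TestWorkedExample:
    def test_example_paragraph_yields_six_hits(
        self, example_i_products, example_i_lexicon
    ):
        """A creatine paragraph mentioning 'rpm' in passing: all three effect
        phrases get attributed to both products (2 x 3 = 6 hits), including
        the false RPM attributions."""
        paragraph = Paragraph("ex#0", 0, EXAMPLE_I_TEXT)
        hits = search_paragraph(paragraph, example_i_products, example_i_lexicon)
        assert len(hits) == 6
        by_product = {}
        for h in hits:
            by_product.setdefault(h.product_canonical, set()).add(
                h.effect.matched_text
            )
        expected = {"meer kracht", "explosieve kracht", "meer uithoudingsvermogen"}
        assert by_product == {"RPM": expected, "creatine": expected}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_hit_set_matches_brute_force(self, seed):
        cfg = SimConfig(
            n_posts=6,
            paragraphs_per_post=(2, 5),
            n_products=4,
            n_brands=2,
            n_effect_terms=6,
            n_type_labels=4,
            plant_rate=0.5,
            confound_rate=0.2,
            multi_product_rate=0.3,
            pattern_rate=0.3,
            seed=seed,
        )
        products, lex = generate_lexicons(cfg)
        posts, _ = generate_corpus(cfg, (products, lex))
        expected = set()
        for post in posts:
            for par in post.paragraphs:
                expected |= brute_force_hits(
                    par.paragraph_id, par.text, products, lex
                )
        assert hit_key_set(search_corpus(posts, products, lex)) == expected


class TestHitsTsv:
    def test_round_trip(self, example_i_products, example_i_lexicon):
        paragraph = Paragraph("ex#0", 0, EXAMPLE_I_TEXT)
        hits = search_paragraph(paragraph, example_i_products, example_i_lexicon)
        buffer = io.StringIO()
        write_hits(hits, buffer)
        again = load_hits(io.StringIO(buffer.getvalue()))
        assert again == hits
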