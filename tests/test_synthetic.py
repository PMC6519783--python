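import math

import pytest

from suppsignal import (
    cohen_kappa,
    confusion,
    annotator_support,
    gold_from_truth,
    prf_accuracy,
    validate_lexicon,
    write_corpus,
)
from suppsignal.matcher import search_corpus
from suppsignal.synthetic import (
    FILLER_WORDS,
    NEGATIONS,
    SimConfig,
    generate_corpus,
    generate_lexicons,
    write_fixtures,
)


class TestLexiconGeneration:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=42)
        assert generate_lexicons(cfg) == generate_lexicons(cfg)

    def test_requested_counts(self):
        cfg = SimConfig(n_products=5, n_brands=2, seed=1)
        products, _ = generate_lexicons(cfg)
        assert sum(1 for e in products if e.kind == "product") == 5
        assert sum(1 for e in products if e.kind == "brand") == 2

    def test_generated_lexicon_is_valid(self):
        _, lex = generate_lexicons(SimConfig(seed=9))
        assert validate_lexicon(lex) == []

    def test_surfaces_disjoint_from_filler(self):
        products, lex = generate_lexicons(SimConfig(seed=3))
        filler = {w.casefold() for w in FILLER_WORDS} | set(NEGATIONS) | {"van"}
        for entry in products:
            assert not (entry.variants & filler)
        for item in lex.vocab:
            assert not (set(item.tokens) & filler)


class TestCorpusGeneration:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_posts=20, seed=14, plant_rate=0.4, confound_rate=0.1)
        lexicons = generate_lexicons(cfg)
        posts_a, truth_a = generate_corpus(cfg, lexicons)
        posts_b, truth_b = generate_corpus(cfg, lexicons)
        assert write_corpus(posts_a) == write_corpus(posts_b)
        assert truth_a.paragraphs == truth_b.paragraphs

    def test_truth_spans_resolve_against_text(self):
        cfg = SimConfig(n_posts=30, plant_rate=0.5, confound_rate=0.3, seed=2)
        products, lex = generate_lexicons(cfg)
        _, truth = generate_corpus(cfg, (products, lex))
        by_canonical = {e.canonical: e for e in products}
        for pt in truth.paragraphs.values():
            for canonical, (start, end) in pt.products:
                assert pt.text[start:end].casefold() in by_canonical[canonical].variants
            for (start, end), _label in pt.effects:
                assert pt.text[start:end]  # non-empty, inside the paragraph

    def test_plant_rate_zero_means_no_positives_and_no_hits(self):
        cfg = SimConfig(n_posts=40, plant_rate=0.0, confound_rate=0.0, seed=5)
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        assert truth.positive_ids() == set()
        assert search_corpus(posts, products, lex) == []

    def test_plant_rate_one_every_paragraph_hits(self):
        cfg = SimConfig(n_posts=25, plant_rate=1.0, confound_rate=0.0, seed=6)
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        hits = search_corpus(posts, products, lex)
        assert {h.paragraph_id for h in hits} == truth.all_ids()

    def test_planted_fraction_within_three_binomial_se(self):
        cfg = SimConfig(
            n_posts=400, paragraphs_per_post=(5, 5), plant_rate=0.3, seed=7
        )
        products, lex = generate_lexicons(cfg)
        _, truth = generate_corpus(cfg, (products, lex))
        n = len(truth.paragraphs)
        assert n == 2000
        fraction = len(truth.positive_ids()) / n
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(fraction - 0.3) <= 3 * se

    def test_sentiment_only_confounds_are_not_retrieved(self):
        cfg = SimConfig(
            n_posts=60, plant_rate=0.3, confound_rate=0.3,
            confound_negated_fraction=0.0, seed=8,
        )
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        retrieved = {h.paragraph_id for h in search_corpus(posts, products, lex)}
        assert retrieved == truth.positive_ids()
        assert truth.ids_of_kind("confound_sentiment")  # config actually fired

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            SimConfig(plant_rate=0.8, confound_rate=0.4)


class TestEndToEndAgainstTruth:
    def test_confound_free_precision_recall_one(self):
        cfg = SimConfig(n_posts=80, plant_rate=0.4, confound_rate=0.0, seed=17)
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        retrieved = {h.paragraph_id for h in search_corpus(posts, products, lex)}
        metrics = prf_accuracy(
            confusion(retrieved, truth.positive_ids(), truth.all_ids())
        )
        assert metrics.precision == 1.0 and metrics.recall == 1.0

    def test_negated_confounds_cost_exactly_their_count_in_precision(self):
        cfg = SimConfig(n_posts=150, plant_rate=0.3, confound_rate=0.2, seed=18)
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        retrieved = {h.paragraph_id for h in search_corpus(posts, products, lex)}
        planted = truth.positive_ids()
        confounds = truth.ids_of_kind("confound_negated")
        assert retrieved == planted | confounds
        metrics = prf_accuracy(confusion(retrieved, planted, truth.all_ids()))
        assert metrics.recall == 1.0
        assert metrics.precision == len(planted) / (len(planted) + len(confounds))


class TestGoldGeneration:
    def _setup(self, noise, seed=31):
        cfg = SimConfig(n_posts=60, plant_rate=0.5, confound_rate=0.0, seed=seed)
        products, lex = generate_lexicons(cfg)
        posts, truth = generate_corpus(cfg, (products, lex))
        hits = search_corpus(posts, products, lex)
        gold = gold_from_truth(truth, noise, 3, seed)
        return hits, gold

    def test_zero_noise_full_support_and_unit_kappa(self):
        hits, gold = self._setup(noise=0.0)
        matches = [h.effect for h in hits]
        assert annotator_support(matches, gold, 3) == {3: 1.0, 2: 1.0, 1: 1.0}
        pids = sorted({g.paragraph_id for g in gold})
        marked = {
            a: {g.paragraph_id for g in gold if g.annotator_id == a}
            for a in ("ann0", "ann1", "ann2")
        }
        kappa = cohen_kappa(
            [p in marked["ann0"] for p in pids], [p in marked["ann1"] for p in pids]
        )
        assert kappa == 1.0

    def test_noise_lowers_support(self):
        hits, gold = self._setup(noise=0.5)
        fractions = annotator_support([h.effect for h in hits], gold, 3)
        assert fractions[3] < 1.0
        assert fractions[3] <= fractions[2] <= fractions[1]

    def test_deterministic_given_seed(self):
        _, gold_a = self._setup(noise=0.3)
        _, gold_b = self._setup(noise=0.3)
        assert gold_a == gold_b


class TestFixtureFiles:
    def test_write_fixtures_round_trips_through_loaders(self, tmp_path):
        from suppsignal import load_effects, load_products, parse_corpus

        cfg = SimConfig(n_posts=10, plant_rate=0.5, confound_rate=0.2, seed=4)
        paths = write_fixtures(cfg, tmp_path, n_annotators=2)
        posts = parse_corpus(paths["corpus"])
        products = load_products(paths["products"])
        lex = load_effects(paths["effects_vocab"], paths["effects_rules"])
        assert posts and products and lex.rules
        assert paths["truth"].read_text(encoding="utf-8").startswith("paragraph_id")
        assert (tmp_path / "gold_0.tsv").exists()
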