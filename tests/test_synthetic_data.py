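"""Generator properties: disjoint categories, seeded determinism, closed-form
token/category frequencies, minimum-length guarantee and chance behavior
when the signal rate is zero."""

import json

import numpy as np
import pytest

from mtlscreen.corpus import TASK_FLAGGED, collapse_risk
from mtlscreen.evaluation import macro_auc
from mtlscreen.lexicon import score_many
from mtlscreen.mtl_model import ModelConfig, SingleTaskNetwork
from mtlscreen.preprocess import CleaningConfig, documents_from_records, filter_min_tokens
from mtlscreen.synthetic_data import (
    GeneratorConfig,
    expected_aux_signal,
    generate_corpus_pair,
    generate_lexicon,
)
from mtlscreen.training import TrainConfig, train_single_task

SMALL = dict(
    vocab_size=500, n_categories=6, terms_per_category=10, n_signal_categories=2,
    n_per_class=40, doc_length_mean=80, min_tokens=50,
)


class TestGenerateLexicon:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_categories_pairwise_disjoint(self, seed):
        lex, _ = generate_lexicon(GeneratorConfig(**SMALL, seed=seed))
        cats = list(lex.categories.values())
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                assert not (cats[i] & cats[j])

    def test_full_overlap_shares_all_signal_terms(self):
        _, man = generate_lexicon(GeneratorConfig(**SMALL, cross_task_overlap=1.0))
        assert man.signal_terms_a == man.signal_terms_b
        assert man.shared_terms == man.signal_terms_a

    def test_zero_overlap_disjoint_signal_sets(self):
        _, man = generate_lexicon(GeneratorConfig(**SMALL, cross_task_overlap=0.0))
        assert not (set(man.signal_terms_a) & set(man.signal_terms_b))

    def test_capacity_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(vocab_size=50, n_categories=6, terms_per_category=10)


class TestGenerateCorpusPair:
    def test_same_seed_byte_identical(self):
        a = generate_corpus_pair(GeneratorConfig(**SMALL, seed=9))
        b = generate_corpus_pair(GeneratorConfig(**SMALL, seed=9))
        assert json.dumps(a.users_a) == json.dumps(b.users_a)
        assert json.dumps(a.users_b) == json.dumps(b.users_b)

    def test_all_users_survive_min_token_filter(self):
        pair = generate_corpus_pair(GeneratorConfig(**SMALL, seed=3))
        cfg = CleaningConfig.for_platform("synthetic", min_tokens=50)
        docs = list(documents_from_records(pair.users_a + pair.users_b, cfg))
        assert len(filter_min_tokens(docs, 50)) == len(docs)

    def test_class_counts_and_risk_labels(self):
        cfg = GeneratorConfig(**SMALL, seed=4)
        pair = generate_corpus_pair(cfg)
        train_a = [u for u in pair.users_a if u["split"] == "train"]
        labels = [u["label"] for u in train_a]
        n_pos = sum(collapse_risk(l, TASK_FLAGGED) for l in labels if l != "control")
        assert n_pos == cfg.n_per_class  # swap noise preserves marginals
        assert set(labels) <= {"none", "low", "moderate", "severe", "control"}

    def test_label_noise_flips_observed_labels(self):
        cfg = GeneratorConfig(**SMALL, seed=5, label_noise=0.2)
        pair = generate_corpus_pair(cfg)
        latent = pair.manifest.latent_class["b"]
        train_b = [u for u in pair.users_b if u["split"] == "train"]
        flips = sum(1 for u in train_b if int(u["label"]) != latent[u["user_id"]])
        assert flips == 2 * round(0.2 * cfg.n_per_class)  # k positives + k negatives

    def test_signal_frequency_matches_mixture_within_3se(self):
        cfg = GeneratorConfig(**SMALL, seed=6, signal_rate=0.3)
        pair = generate_corpus_pair(cfg)
        latent = pair.manifest.latent_class["a"]
        sig = set(pair.manifest.signal_terms_a)
        token_index = {t: i for i, t in enumerate(cfg.tokens)}
        bg_sig_mass = sum(cfg.background_probs[token_index[t]] for t in sig)
        expected = cfg.signal_rate + (1 - cfg.signal_rate) * bg_sig_mass
        n_sig = n_tot = 0
        for u in pair.users_a:
            if latent[u["user_id"]] != 1:
                continue
            toks = " ".join(p["text"] for p in u["posts"]).split()
            n_sig += sum(1 for t in toks if t in sig)
            n_tot += len(toks)
        se = np.sqrt(expected * (1 - expected) / n_tot)
        assert abs(n_sig / n_tot - expected) < 3 * se


class TestExpectedAuxSignal:
    def test_closed_form_matches_monte_carlo(self):
        cfg = GeneratorConfig(**SMALL, seed=7, signal_rate=0.25)
        pair = generate_corpus_pair(cfg)
        exp = expected_aux_signal(cfg, pair.manifest)
        latent = pair.manifest.latent_class["a"]
        clean = CleaningConfig.for_platform("synthetic", min_tokens=50)
        docs = list(documents_from_records(pair.users_a, clean))
        pos = [d for d in docs if latent[d.user_id] == 1]
        ctl = [d for d in docs if latent[d.user_id] == 0]
        feats_pos = score_many(pos, pair.lexicon)
        feats_ctl = score_many(ctl, pair.lexicon)
        order = pair.lexicon.category_order
        n_tok = cfg.doc_length_mean
        for j, cat in enumerate(order):
            for feats, key in ((feats_pos, "positive_a"), (feats_ctl, "control")):
                mean = feats[:, j].mean()
                e = exp[cat][key]
                se = np.sqrt(max(e * (1 - e), 1e-9) / (n_tok * len(feats)))
                assert abs(mean - e) < 4 * se, (cat, key, mean, e)

    def test_signal_category_enriched_in_positives(self):
        cfg = GeneratorConfig(**SMALL, signal_rate=0.3)
        _, man = generate_lexicon(cfg)
        exp = expected_aux_signal(cfg, man)
        for cat in man.signal_categories_a:
            assert exp[cat]["positive_a"] > exp[cat]["control"]


class TestChanceBehaviorWithoutSignal:
    def test_zero_signal_rate_gives_chance_auc(self):
        """With pi = 0 positives and controls are exchangeable; a trained
        classifier's AUC on a large fresh sample must sit near 0.5 (3 seeds)."""
        from mtlscreen.corpus import build_vocabulary, encode_documents

        clean = CleaningConfig.for_platform("synthetic", min_tokens=50)

        def encoded(seed, vocab=None, max_len=60):
            cfg = GeneratorConfig(
                **{**SMALL, "n_per_class": 100}, seed=seed,
                signal_rate=0.0, label_noise=0.0,
            )
            pair = generate_corpus_pair(cfg)
            docs = [
                d for d, u in zip(documents_from_records(pair.users_a, clean), pair.users_a)
                if u["split"] == "train" and str(d.label) != "control"
            ]
            if vocab is None:
                vocab = build_vocabulary(docs, [], max_size=cfg.vocab_size)
            X = encode_documents(docs, vocab, max_len)
            y = np.array([collapse_risk(d.label, TASK_FLAGGED) for d in docs])
            return X, y, vocab, cfg

        aucs = []
        for seed in (0, 1, 2):
            X, y, vocab, cfg = encoded(seed)
            Xt, yt, _, _ = encoded(seed + 100, vocab=vocab)
            net = SingleTaskNetwork(
                ModelConfig(vocab_size=cfg.vocab_size, max_len=60, embed_dim=8,
                            n_filters=6, dense_units=8), seed=seed)
            n_tr = int(0.8 * len(X))
            net, _ = train_single_task(
                net, ((X[:n_tr], y[:n_tr]), (X[n_tr:], y[n_tr:])),
                TrainConfig(max_epochs=4, batch_size=8, seed=seed))
            p = net.forward(Xt, train=False)
            aucs.append(macro_auc(yt, p[:, 1]))
        assert abs(np.mean(aucs) - 0.5) < 0.08
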