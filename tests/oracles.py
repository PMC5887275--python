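"""Independent brute-force reimplementations used as test oracles.

Everything here is computed directly from the raw records (tokenized on
the fly) with plain dictionaries and loops, deliberately sharing no
code path with the index- or search-side implementations it checks.
"""

from __future__ import annotations

import math
from collections import Counter

from dsearch.index_core import tokenize

FIELDS = ("title", "text", "metadata")


def field_tokens(record, field):
    if field == "whole":
        return (tokenize(record.title) + tokenize(record.text)
                + tokenize(record.metadata))
    return tokenize(getattr(record, field))


def brute_force_scores(records, weighted_terms, cfg):
    """Score every document: sum over terms of weight * sum over fields
    of field_weight * BM25, everything recomputed from the records."""
    n = len(records)
    avg_len = {}
    df = {}
    for f in FIELDS:
        toks = {r.docno: field_tokens(r, f) for r in records}
        avg_len[f] = sum(len(t) for t in toks.values()) / n
        df[f] = Counter()
        for t in toks.values():
            df[f].update(set(t))
    scores = {}
    for r in records:
        counts = {f: Counter(field_tokens(r, f)) for f in FIELDS}
        lens = {f: sum(counts[f].values()) for f in FIELDS}
        s = 0.0
        for term, weight in weighted_terms:
            for f in FIELDS:
                w_f = cfg.field_weights.get(f, 0.0)
                tf = counts[f][term]
                if w_f == 0.0 or tf == 0:
                    continue
                idf = math.log(1 + (n - df[f][term] + 0.5) / (df[f][term] + 0.5))
                norm = tf * (cfg.k1 + 1) / (
                    tf + cfg.k1 * (1 - cfg.b + cfg.b * lens[f] / avg_len[f]))
                s += weight * w_f * idf * norm
        scores[r.docno] = s
    return scores


def brute_force_search(records, weighted_terms, cfg):
    scores = brute_force_scores(records, weighted_terms, cfg)
    ranked = sorted(((d, s) for d, s in scores.items() if s > 0),
                    key=lambda item: (-item[1], item[0]))
    return ranked[: cfg.top_k]


def brute_force_wig(records, query_terms, n_top, mu, cfg):
    """Direct evaluation of the WIG formula from raw records."""
    coll = Counter()
    whole = {}
    for r in records:
        whole[r.docno] = field_tokens(r, "whole")
        coll.update(whole[r.docno])
    total = sum(coll.values())
    wigs = {}
    for term in dict.fromkeys(query_terms):
        p_c = coll[term] / total
        if p_c == 0:
            wigs[term] = -math.inf
            continue
        top = [d for d, _ in brute_force_search(records, [(term, 1.0)], cfg)[:n_top]]
        logs = []
        for d in top:
            tf = Counter(whole[d])[term]
            logs.append(math.log((tf + mu * p_c) / (len(whole[d]) + mu)))
        wigs[term] = (sum(logs) / len(logs) - math.log(p_c)) / (-math.log(p_c))
    return wigs


def brute_force_features(records, query_tokens, docno, cfg):
    """Single-pass recomputation of all 22 ranking features."""
    n = len(records)
    by_docno = {r.docno: r for r in records}
    rec = by_docno[docno]
    tokens = list(dict.fromkeys(query_tokens))
    all_fields = FIELDS + ("whole",)
    toks = {f: {r.docno: field_tokens(r, f) for r in records} for f in all_fields}
    feats = {}
    key = {"title": "Title", "text": "Text", "metadata": "Meta", "whole": "Whole"}
    for f in all_fields:
        counts = Counter(toks[f][docno])
        df = Counter()
        for t in toks[f].values():
            df.update(set(t))
        avg = sum(len(t) for t in toks[f].values()) / n
        bm25 = tf_s = idf_s = tfidf_s = 0.0
        for term in tokens:
            tf = counts[term]
            if tf == 0:
                continue
            idf_f = math.log(n / (df[term] + 1)) + 1
            tf_s += tf
            idf_s += idf_f
            tfidf_s += tf * idf_f
            idf_b = math.log(1 + (n - df[term] + 0.5) / (df[term] + 0.5))
            bm25 += idf_b * tf * (cfg.k1 + 1) / (
                tf + cfg.k1 * (1 - cfg.b + cfg.b * len(toks[f][docno]) / avg))
        feats["BM25" if f == "whole" else f"BM25{key[f]}"] = bm25
        suffix = key[f]
        feats[f"1GramTF{suffix}"] = tf_s
        feats[f"1GramIDF{suffix}"] = idf_s
        feats[f"1GramTFIDF{suffix}"] = tfidf_s
        q_bigrams = set(zip(tokens, tokens[1:]))
        d_bigrams = set(zip(toks[f][docno], toks[f][docno][1:]))
        feats[f"2Grams{suffix}"] = float(len(q_bigrams & d_bigrams))
    text = toks["text"][docno]
    positions = [i for i, t in enumerate(text) if t in set(tokens)]
    feats["DistanceFromStart"] = float(min(positions) if positions else len(text))
    repo_counts = Counter(r.repository for r in records)
    feats["DomainWeight"] = repo_counts[rec.repository] / n
    return feats


def naive_ndcg(ordered_docnos, judged, k):
    """judged: docno -> grade mapping for one query."""
    dcg = 0.0
    for i, d in enumerate(ordered_docnos[:k]):
        dcg += (2 ** judged.get(d, 0) - 1) / math.log2(i + 2)
    ideal = sorted(judged.values(), reverse=True)[:k]
    idcg = sum((2 ** g - 1) / math.log2(i + 2) for i, g in enumerate(ideal))
    return dcg / idcg if idcg > 0 else 0.0


def naive_ap(ordered_docnos, judged):
    relevant = {d for d, g in judged.items() if g >= 1}
    if not relevant:
        return 0.0
    hits = 0
    total = 0.0
    for i, d in enumerate(ordered_docnos, start=1):
        if d in relevant:
            hits += 1
            total += hits / i
    return total / len(relevant)


def naive_p10(ordered_docnos, judged):
    return sum(1 for d in ordered_docnos[:10] if judged.get(d, 0) >= 1) / 10
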