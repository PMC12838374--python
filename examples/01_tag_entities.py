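"""Train the reference tagger on a synthetic corpus and tag a held-out report.

Builds a small annotated corpus, trains the windowed softmax tagger on 80%
of it, and prints the entities decoded from one unseen report next to the
gold annotations.  The tags are token-level BIO labels; decoding repairs
any illegal I- continuation into a span start.
"""

from pathocode.ner import NERConfig, SplitSpec, split_reports, tag_report, train_tagger
from pathocode.synthetic import GeneratorConfig, NoiseConfig, generate_reports

cfg = GeneratorConfig(n_reports=120, n_concepts=10, seed=7, noise=NoiseConfig.none())
reports = generate_reports(cfg)
train, test = split_reports(reports, SplitSpec(train_fraction=0.8, seed=7))

tagger = train_tagger(train, NERConfig(seed=7))
report = test[0]
_, mentions = tag_report(tagger, report)

print(f"report {report.report_id} ({report.language}): {report.text}\n")
print(f"{'predicted':<42} {'type':<15}")
for m in mentions:
    print(f"{m.surface:<42} {m.entity_type:<15}")
print(f"\ngold mentions: {[(e.surface, e.entity_type) for e in report.entities]}")
# On a clean corpus the predicted spans should reproduce the gold spans:
# every surface/type pair above should appear in the gold list.
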