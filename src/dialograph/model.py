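"""Model/Results surface over the full pipeline.

`DepressionGraphModel` is built from split transcripts (or a synthetic
corpus), holds the graph variant and architecture choices, and `fit()` runs
the multi-seed training protocol, returning a `DepressionGraphResults`
carrying per-seed and aggregated metrics with a printable `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .embeddings import EncoderSpec
from .io import Transcript
from .nn import ModelConfig
from .synth import SyntheticCorpus
from .training import (EvalReport, TrainConfig, majority_baseline_metrics,
                       prepare_datasets, run_protocol, train_model)

__all__ = ["DepressionGraphModel", "DepressionGraphResults"]


class DepressionGraphModel:
    """Binary depression-status classifier over graph-encoded interviews.

    Parameters
    ----------
    transcripts_by_split : dict with "train", "dev", "test" transcript lists
    variant : one of similarity_baseline, similarity_mv, kcg_baseline, kcg_mv
    model_config : architecture settings; defaults to the variant's defaults
    encoder_spec : sentence-encoder backend (deterministic by default)
    """

    def __init__(self,
                 transcripts_by_split: dict[str, list[Transcript]],
                 variant: str = "similarity_mv",
                 model_config: Optional[ModelConfig] = None,
                 encoder_spec: Optional[EncoderSpec] = None):
        for split in ("train", "dev", "test"):
            if split not in transcripts_by_split:
                raise ValueError(f"missing split {split!r}")
        self.transcripts_by_split = transcripts_by_split
        self.variant = variant
        self.model_config = model_config or ModelConfig(variant=variant)
        self.encoder_spec = encoder_spec or EncoderSpec(dim=64)

    @classmethod
    def from_corpus(cls, corpus: SyntheticCorpus, variant: str = "similarity_mv",
                    **kwargs) -> "DepressionGraphModel":
        splits = {name: corpus.subset(name) for name in ("train", "dev", "test")}
        return cls(splits, variant=variant, **kwargs)

    def fit(self, train_config: TrainConfig = TrainConfig()) -> "DepressionGraphResults":
        report = run_protocol(self.transcripts_by_split, self.variant,
                              train_config=train_config,
                              model_config=self.model_config,
                              encoder_spec=self.encoder_spec)
        return DepressionGraphResults(model=self, report=report,
                                      train_config=train_config)

    def refit_single(self, seed: int = 0,
                     train_config: TrainConfig = TrainConfig(),
                     similarity_threshold: float = 0.5):
        """Train one classifier at a fixed threshold (no grid, no protocol)."""
        datasets = prepare_datasets(
            self.transcripts_by_split, self.variant,
            encoder_spec=self.encoder_spec,
            similarity_threshold=similarity_threshold,
            kcg_threshold=train_config.kcg_threshold,
            n_topics=train_config.n_topics,
            top_k_keywords=train_config.top_k_keywords)
        model, history = train_model(datasets, self.model_config,
                                     train_config, seed=seed)
        return model, history, datasets


@dataclass
class DepressionGraphResults:
    model: DepressionGraphModel
    report: EvalReport
    train_config: TrainConfig

    @property
    def aggregate(self) -> dict:
        return self.report.aggregate()

    def per_seed(self) -> pd.DataFrame:
        return self.report.to_dataframe()

    def majority_baseline(self) -> dict[str, float]:
        train_labels = [t.label for t in
                        self.model.transcripts_by_split["train"]]
        test_labels = [t.label for t in
                       self.model.transcripts_by_split["test"]]
        return majority_baseline_metrics(train_labels, test_labels)

    def summary(self) -> str:
        agg = self.aggregate
        rows = []
        for split in ("dev", "test"):
            for metric in ("macro_f1", "uar", "accuracy", "macro_precision"):
                cell = agg[f"{split}_{metric}"]
                rows.append({"split": split, "metric": metric,
                             "mean": round(cell["mean"], 3),
                             "std": round(cell["std"], 3)})
        table = pd.DataFrame(rows).to_string(index=False)
        head = (f"DepressionGraphModel  variant={self.report.variant}  "
                f"seeds={list(self.train_config.seeds)}  "
                f"threshold={self.report.chosen_threshold}")
        return head + "\n" + table + "\n"
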