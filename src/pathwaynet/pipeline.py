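"""End-to-end convenience wiring: cohort -> preprocessing -> model -> metrics."""

from __future__ import annotations

from .cohort import CohortDataset
from .hierarchy import MaskStack
from .metrics import MetricsReport
from .model import ConstrainedPathwayClassifier, DenseBaselineClassifier, ModelConfig
from .preprocessing import preprocess_cohort

__all__ = ["train_and_evaluate"]


def train_and_evaluate(
    dataset: CohortDataset,
    mask_snp: MaskStack,
    mask_expr: MaskStack,
    config: ModelConfig | None = None,
    seed: int = 0,
    baseline: bool = False,
):
    """Preprocess, train and score on the held-out test split.

    Returns ``(model, processed, report)``.  The same ``seed`` drives the
    split, SMOTE and weight initialisation, so two calls on the same cohort
    are fully reproducible.
    """
    config = config or ModelConfig(seed=seed)
    processed = preprocess_cohort(dataset, seed=seed)
    cls = DenseBaselineClassifier if baseline else ConstrainedPathwayClassifier
    model = cls(
        mask_snp=mask_snp, mask_expr=mask_expr,
        subnetwork_activation=config.subnetwork_activation,
        hidden1_size=config.hidden1_size, hidden2_size=config.hidden2_size,
        dropout_rate=config.dropout_rate, l2=config.l2,
        learning_rate=config.learning_rate, decay_rate=config.decay_rate,
        decay_steps=config.decay_steps, batch_size=config.batch_size,
        max_epochs=config.max_epochs, patience=config.patience,
        random_state=seed,
    )
    model.fit(
        processed.X_train, processed.y_train,
        validation_data=(processed.X_val, processed.y_val),
    )
    report: MetricsReport = model.evaluate(processed.X_test, processed.y_test)
    return model, processed, report
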