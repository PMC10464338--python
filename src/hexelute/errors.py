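"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input table, sequence or configuration violates its contract."""


class PipelineOrderError(RuntimeError):
    """A processing stage was invoked out of the enforced order.

    The quantification chain must run as: high-confidence filter ->
    detection filter -> minimum imputation -> quantile normalization ->
    log2 / Z-scoring. Each stage records itself on the table it returns
    and refuses to run unless its predecessors have run.
    """
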