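"""Pipeline configuration, seeding, and provenance.

Defaults of every full-scale constant match the published design: 512-px
morphology patches resized to 448, 1024-px mutation patches resized to 224,
tissue fraction threshold 0.2, annotation fraction 0.75, classification
threshold 0.5, confidence band 0.25/0.75, morphology training 15 epochs,
mutation training up to 200 epochs, MIL bag size 40, Adam learning rate
1e-5, splits 0.8 mutant training fraction / 15% validation prevalence /
5 folds.

The ``demo_*`` fields define the reduced desk-scale study (slide size,
patch geometry, cohort size, epochs, learning rate) used by the synthetic
end-to-end run; they are package choices documented in the methods note.

A single global seed fans out to stage-specific seeds via
``stage_seed(seed, stage)`` = SHA-256 of ``"{seed}:{stage}"`` reduced
mod 2**31, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    # full-scale patch geometry
    morphology_patch_size: int = 512
    morphology_input_size: int = 448
    mutation_patch_size: int = 1024
    mil_input_size: int = 224
    # thresholds
    min_tissue_fraction: float = 0.2
    min_annotation_fraction: float = 0.75
    classification_threshold: float = 0.5
    confidence_low: float = 0.25
    confidence_high: float = 0.75
    # masking
    mask_downsample: int = 16
    saturation_threshold: float = 0.07
    mask_min_object_px: int = 64
    mask_min_hole_px: int = 64
    # training
    morphology_epochs: int = 15
    mutation_epochs: int = 200
    mil_epochs: int = 200
    bag_size: int = 40
    learning_rate: float = 1e-5
    early_stopping_patience: int = 20
    # splits
    n_folds: int = 5
    mutant_train_frac: float = 0.8
    val_prevalence: float = 0.15
    # review
    review_bags: int = 49
    review_patches_per_bag: int = 250
    review_top_k: int = 25
    # global seed
    seed: int = 0

    # ---- desk-scale demo study (reduced problem sizes) ----
    demo_slide_size: int = 1024
    demo_mutation_patch_size: int = 128
    demo_model_input_size: int = 64
    demo_morphology_patch_size: int = 64
    demo_morphology_input_size: int = 56
    demo_n_mutant: int = 60
    demo_n_wildtype: int = 60
    demo_mutant_train_frac: float = 2.0 / 3.0
    demo_val_prevalence: float = 0.5
    demo_morphology_patches_per_class: int = 250
    demo_mutation_epochs: int = 60
    demo_mil_epochs: int = 50
    demo_patience: int = 15
    demo_learning_rate: float = 1e-3
    demo_signal_strength: float = 1.5
    demo_signal_penetrance: float = 0.70
    demo_max_patches_per_slide: int = 24
    demo_immune_boost_wildtype: float = 2.0
    demo_mask_downsample: int = 8
    demo_mask_min_object_px: int = 8
    demo_mask_min_hole_px: int = 8

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Short digest recorded in every output for provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
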