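# Full training protocol as published for the real endoscopy datasets:
# AdamW (lr 1e-3, batch 8), cosine annealing over 300 epochs, BceDice with
# alpha = beta = 1, random rotation + horizontal/vertical flips, images
# resized to 256x256, 80/10/10 train/val/test split.
# Point `data` at a local copy of a polyp dataset (e.g. Kvasir-SEG) to run:
#   mgraunet train --config configs/published_protocol.yaml --out runs/full
seed: 0
epochs: 300
batch_size: 8
learning_rate: 0.001
weight_decay: 0.01
image_size: 256
loss:
  alpha: 1.0
  beta: 1.0
augment:
  rotation_range: 90.0
  flip_prob: 0.5
split:
  ratios: [0.8, 0.1, 0.1]
data:
  image_dir: /path/to/dataset/images
  mask_dir: /path/to/dataset/masks
network: {}  # package defaults
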