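"""Build each detector variant and print its complexity budget.

The point of the lightweight redesign is visible directly in the counts: the
MobileViT-reconstructed backbone drops the parameter count by ~61% relative
to the YOLOv8n baseline, LSK attention adds a few thousand parameters back,
and GSConv trims the neck. FLOPs are one 640x640 forward pass with each
multiply-accumulate counted as two operations.
"""
from mlgyolo import summarize

for variant in ("yolov8n", "yolov8n-lsk", "yolov8n-gsconv", "mobilevit",
                "mobilevit-lsk", "mobilevit-gsconv", "mlg-yolo"):
    r = summarize(variant)
    print(f"{variant:18s} params {r.parameters:>9,}   FLOPs {r.gflops:5.2f} G"
          f"   fp16 size {r.size_mb_fp16:4.2f} MB")

base = summarize("yolov8n").parameters
full = summarize("mlg-yolo").parameters
print(f"\nparameter reduction of the full model vs baseline: "
      f"{100 * (base - full) / base:.2f}%")
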