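"""Parameter and FLOP accounting: SD-UNet vs. the baseline U-Net.

Builds both graphs for a 256 x 256 grayscale input and prints their
trainable-parameter totals, FLOPs under the kernel-weight convention
(2 operations per convolution kernel weight), and the fold reductions —
the factorization's headline efficiency numbers.
"""

from sdunet import ModelConfig, build_sd_unet, build_unet, model_accounting
from sdunet.cost_model import ConvCostSpec, cost_reduction_ratio

cfg = ModelConfig(input_height=256, input_width=256, input_channels=1)
sd = model_accounting(build_sd_unet(cfg))
unet = model_accounting(build_unet(cfg))

print(f"SD-UNet : {sd.params_millions}M params, "
      f"{sd.paper_flops_millions}M FLOPs, {sd.size_in_memory_mb} MB weights")
print(f"U-Net   : {unet.params_millions}M params, "
      f"{unet.paper_flops_millions}M FLOPs, {unet.size_in_memory_mb} MB weights")

ratios = sd.ratio_to(unet)
print(f"reduction: {1 / (sd.total_params / unet.total_params):.2f}x fewer "
      f"parameters, {ratios['paper_flops']:.2f}x the FLOPs of SD-UNet in U-Net")

# the per-layer closed form at deep-layer width: Dk^2 N / (Dk^2 + N)
r = cost_reduction_ratio(ConvCostSpec(Dk=3, M=512, N=512))
print(f"single 3x3 layer at 512 channels: {r:.3f}x cheaper when factorized")
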