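"""Parameter accounting of shared vs non-shared convolution stacks.

A conv layer with n_in input maps, n_out output maps and a Kh x Kw kernel
trains n_in*n_out*Kh*Kw + n_out parameters.  Training a separate stack per
axis picture triples the cost; sharing one stack across the three pictures
keeps it flat — that threefold saving is the point of the shared variants.
"""

from har2dcnn import NetworkSpec, count_conv_params, count_layer_params, reference_stack

stack = reference_stack(maps=64)
print("reference stack, per-layer trainable parameters:")
for layer in stack:
    kh, kw = layer.kernel
    print(f"  {layer.name}: {kh}x{kw}, {layer.in_maps}->{layer.out_maps} maps "
          f"-> {count_layer_params(layer)}")

spec = lambda shared: NetworkSpec(axis_rows=16, window=24, conv_stack=stack,
                                  n_classes=5, shared=shared)
non_shared = count_conv_params(spec(False))
shared = count_conv_params(spec(True))
print(f"three independent stacks (T-2DCNN): {non_shared}")
print(f"one shared stack (TS-2DCNN):       {shared}")
print(f"ratio: {non_shared // shared}x fewer convolution parameters when shared")
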