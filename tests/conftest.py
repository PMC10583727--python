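import trihet

# not a test class despite the name
trihet.TestSpec.__test__ = False
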