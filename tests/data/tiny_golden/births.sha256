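830cd304457f6a0ebfb6c85b521f757452609012648214d8a40ad832a4485a0d
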