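>a
AAAAAAAAAAA
>b
A-AAA-AA--A
>c
A--A---AA--
>d
---A----A--
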