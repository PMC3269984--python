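>dpu-MIR156a conserved plant mature miRNA (Digitalis purpurea)
UGACAGAAGAGAGGGAGCAC
>dpu-MIR156b conserved plant mature miRNA (Digitalis purpurea)
UGACAGAAGAGAGUGAGCAC
>dpu-MIR160 conserved plant mature miRNA (Digitalis purpurea)
UGCCUGGCUCCUUGUAUGCCA
>dpu-MIR166a conserved plant mature miRNA (Digitalis purpurea)
UCGGACCAGGCUUCAUUCCUC
>dpu-MIR166b conserved plant mature miRNA (Digitalis purpurea)
UCGGACCAGGCUUCAUUCCCC
>dpu-MIR167a conserved plant mature miRNA (Digitalis purpurea)
UGAAGCUGCCAGCAUGAUCUA
>dpu-MIR167b conserved plant mature miRNA (Digitalis purpurea)
UGAAGCUGCCAGCAUGAUCUA
>dpu-MIR167c conserved plant mature miRNA (Digitalis purpurea)
UGAAGCUGCCAGCAUGAUCUG
>dpu-MIR172a conserved plant mature miRNA (Digitalis purpurea)
AGAAUCUUGAUGAUGCUGCAU
>dpu-MIR172b conserved plant mature miRNA (Digitalis purpurea)
AGAAUCUUGAUGAUGCUGCAU
>dpu-MIR396 conserved plant mature miRNA (Digitalis purpurea)
UUCCACAGCUUUCUUGAACUG
>dpu-MIR397 conserved plant mature miRNA (Digitalis purpurea)
CCAUUGAGUGCAGCGUUGAUG
>dpu-MIR408 conserved plant mature miRNA (Digitalis purpurea)
CUGCACUGCCUCUUCCCUGGC
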