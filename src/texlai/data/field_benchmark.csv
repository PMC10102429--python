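family,split,input_set,R2,RMSE,RPD
SVM,Cal,VIs,0.698,0.371,1.487
SVM,Cal,TIs,0.735,0.348,1.656
SVM,Cal,VIs+TIs,0.806,0.315,1.856
SVM,Val,VIs,0.621,0.433,1.338
SVM,Val,TIs,0.790,0.312,2.010
SVM,Val,VIs+TIs,0.813,0.297,2.084
BPNN,Cal,VIs,0.648,0.403,1.335
BPNN,Cal,TIs,0.689,0.380,1.445
BPNN,Cal,VIs+TIs,0.791,0.311,1.899
BPNN,Val,VIs,0.664,0.392,1.716
BPNN,Val,TIs,0.688,0.389,1.787
BPNN,Val,VIs+TIs,0.795,0.330,1.936
RF,Cal,VIs,0.840,0.271,2.257
RF,Cal,TIs,0.844,0.269,2.095
RF,Cal,VIs+TIs,0.906,0.208,3.149
RF,Val,VIs,0.733,0.396,1.545
RF,Val,TIs,0.699,0.411,1.399
RF,Val,VIs+TIs,0.786,0.347,1.888
PLSR,Cal,VIs,0.649,0.402,1.392
PLSR,Cal,TIs,0.652,0.397,1.405
PLSR,Cal,VIs+TIs,0.753,0.335,1.755
PLSR,Val,VIs,0.616,0.413,1.328
PLSR,Val,TIs,0.660,0.425,1.474
PLSR,Val,VIs+TIs,0.759,0.347,1.775
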