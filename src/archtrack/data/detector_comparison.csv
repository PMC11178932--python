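model,instances,tp,fp,tn,fn,recall_printed,precision_printed,accuracy_printed
yolov8x,15305,15224,12,0,69,99.92,99.55,99.92
detectron2,15305,14466,839,0,0,94.52,100.0,94.52
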